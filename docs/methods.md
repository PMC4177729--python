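# Methods

## Model and assumptions

The engine scores a patient sample by (1) normalising each piece of lesion
evidence into a unified `Aberration` record, (2) matching aberrations against a
22-category knowledge base (KB), (3) averaging the matched categories'
traffic-light weights (red 3, amber 2, green 1), and (4) banding the mean into
four risk strata. The mean — rather than a sum — keeps the score independent of
how exhaustively a sample was assayed: detecting more lesions of the same
category, or assaying more categories of the same group, cannot inflate the
score, only shift it toward the weights of what was actually found. The model
assumes gene symbols are the unit of sequence evidence (no coordinates, no
per-mutation functional impact) and that the KB's category granularity is the
right level at which lesions are exchangeable.

Two consequences of the mean are deliberate model behaviour, not bugs, and are
pinned by regression tests: a favourable (green) match dilutes an otherwise
all-red sample, and a sample with no matched lesions has **no** score
("unscorable") rather than a low one — absence of model lesions is not evidence
of low risk.

## Knowledge base

The default KB (`src/ragmm/data/default_kb.yaml`, version `2014.1`) carries the
22 categories with their candidate genes, event class (initiation/primary for
hyperdiploidy and the five primary IGH translocations; progression/secondary
for the rest), cytogenetic patterns for karyotypic categories, and evidence
level/grade metadata. The red/amber/green membership is a reconstruction from
the model's stated tiering rules (adverse → red, favourable → green, neutral →
amber, t(4;14) demoted to amber given bortezomib-era survival); this is
recorded in the KB's `provenance` field, and the KB ships as data precisely so
users can re-tier without code changes. Every scoring output embeds the KB
version. Evidence levels are likewise reconstructed metadata: grade A
throughout, level I for trial-backed FISH lesions, II for other cytogenetic
rows, III for functional categories included on functional characterisation
and mutational recurrence.

Gene matching is case-insensitive and whitespace-stripped; the KB has an
optional alias table (empty by default, i.e. the model's legacy spellings
MMSET, BLIMP1, c-MAF, NIK, TACI, MLL are the vocabulary). "Bone disease"
(DKK1, FRZB) defaults to amber although its independent prognostic weight is
unestablished; hypodiploidy is not a KB category and therefore never matches.

## Matching conventions

- Cytogenetic aberrations match by canonical descriptor against a category's
  pattern. Descriptors are normalised first (`T(4, 14)` → `t(4;14)`,
  `del17p` → `del(17p)`, `1q+` → `+1q`, `+9` → trisomy `9`); `Del(13/13q)`
  accepts both `del(13)` and `del(13q)`.
- Any single trisomy from {1,3,5,7,9,11,15,19,21} matches Hyperdiploidy;
  multiple trisomies aggregate as supporting evidence of the one match. (The
  generator always emits ≥2 trisomies per hyperdiploid patient, the clinically
  typical presentation.)
- Mutations match by candidate gene among pattern-less (functional) categories
  only — the dual-listing resolution: karyotypic disruption and independent
  mutation of the same gene are different events. The functional categories
  have pairwise-disjoint gene sets, so a mutation maps to at most one category.
- Mutations explicitly annotated synonymous never match, regardless of entry
  path; unmatched aberrations are returned in a side list, never dropped.

## VCF handling

`parse_vcf` reads annotated VCF 4.x through cyvcf2, taking gene symbols from a
pipe-delimited INFO annotation (SnpEff/VEP `ANN`/`CSQ` dialect; gene at
configurable subfield, consequence term at position 1) or from a plain
`GENE=`-style key. Per record–gene pair, the worst annotated consequence wins
(nonsynonymous > unknown > synonymous); pairs that are only synonymous are
dropped and counted, so kept + filtered = gene-annotated pairs. Unknown
consequences are kept (conservative inclusion: silent mutations are expected
to be rare among the model's recurrently mutated genes). Multi-allelic records
contribute one unit per distinct gene; duplicates collapse at category level
during scoring anyway.

## Numerical choices

Scores are computed as exact rationals (integer weight sum / match count), so
classification at the band boundaries 1.5 / 2.0 / 2.5 is exact; bands are
lower-inclusive half-open intervals with the top band closed at 3.0, giving a
deterministic, total classification of [1.0, 3.0]. ISS staging uses the strict
inequalities β2m < 3.5 with albumin ≥ 3.5 (stage I) and β2m ≥ 5.5 (stage III),
stage II otherwise — covering both stage-II variants (low β2m with low albumin;
β2m in [3.5, 5.5) irrespective of albumin). Pizza-plot sector angles are exact
rationals 360·w/Σw, ordered red → amber → green and alphabetically within a
group, clockwise from twelve o'clock; rendering is a pure function of the spec
(fixed palette #d7191c/#fdae61/#1a9641, no timestamps or random ids), so equal
specs produce byte-identical SVG. The subset-extremes enumeration
(`score_extremes`) iterates per-group match-count triples with Fraction
arithmetic; every non-empty subset of the categories induces exactly one
triple and every triple is realizable, so the extremes equal full subset
enumeration at negligible cost.

## Synthetic cohorts

`generate_cohort` emulates a diagnostic cohort: each category is sampled
independently per patient from its prevalence (default uniform 0.1 — no
published lesion frequencies accompany the model, so a flat placeholder is
used and any real panel should override it), then adverse categories are
re-drawn at `min(1, p × boost)` (default boost 2) for patients already
carrying an adverse lesion, reproducing the observed co-segregation of adverse
lesions. Sampled categories are realized as concrete lesions (FISH
translocations/deletions/gains with canonical descriptors; a random ≥2-subset
of the odd trisomies for Hyperdiploidy; a sequencing mutation in a random
candidate gene for functional categories). One synonymous decoy mutation is
injected per patient with probability `synonymous_rate` (default 0.05); the
decoy gene is drawn unconditionally so cohorts differing only in decoy rate
share identical category memberships. Clinical values are log-normal —
β2-microglobulin LN(ln 4.3, 0.55) mg/L, albumin LN(ln 3.9, 0.15) g/dL — placing
roughly a third of patients in each ISS stage so all staging branches are
exercised. All randomness flows from one `random.Random(seed)` stream
(platform-stable), so fixed seeds reproduce cohorts byte-for-byte.

The generator's ground truth records each patient's intended category set and
exact expected mean score, making the end-to-end property — write fixtures,
re-parse, match, score, recover every ground truth exactly — checkable at
cohort scale (the test suite uses 500 patients, which runs in seconds). What
passing does **not** show: the generator produces clean, canonical notation
and unambiguous single-gene annotations; real FISH reports, karyotype strings
and VCF annotations are messier (multi-transcript annotations, panel-specific
probe names, subclonal calls), and clinical validity of the score itself is
untested by construction — the model is a concept system, not a validated
prognostic instrument.

## Known limitations

- No survival modelling, treatment recommendation, GEP signature scoring or
  per-mutation functional-impact prediction; published survival figures for
  the risk groups are external-trial outcomes and are not reproduced here.
- Structural lesions seen as sequencing CNV calls have no dedicated entry
  route; the lesion table accepts `method=sequencing` on cytogenetic kinds as
  an extension point.
- The default tiering and evidence metadata are reconstructions (see KB
  provenance) and are expected to be revised as evidence accrues; edit the KB
  YAML and pass it via `--kb` / `load_kb`.
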