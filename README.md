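# ragmm — Red-Amber-Green genetic risk stratification for multiple myeloma

Multiple myeloma is genetically heterogeneous: hyperdiploid and IGH-translocated
subtypes, secondary chromosome-arm gains/deletions and recurrently mutated driver
genes all carry different prognoses. `ragmm` implements a traffic-light ("RAG")
risk-scoring engine that compresses a patient's detected lesions — FISH/karyotype
cytogenetics plus gene-annotated sequencing variants — into a single score, for
clinical scientists and bioinformaticians building myeloma genomic reports.

## The model

A 22-category knowledge base maps every lesion class of interest
(hyperdiploid trisomies {1,3,5,7,9,11,15,19,21}; the IGH translocations
t(4;14), t(6;14), t(11;14), t(14;16), t(14;20); +1q; seven deletions; the
secondary t(8;14); and seven functional mutation categories such as
Proliferation = {NRAS, KRAS, BRAF, MYC}) to a traffic-light group with weight

- **red** w = 3.0 (adverse: del(17p), t(14;16), t(14;20), +1q),
- **amber** w = 2.0 (intermediate, including t(4;14) in the bortezomib era),
- **green** w = 1.0 (favourable: hyperdiploidy, t(11;14), t(6;14)).

For a sample whose lesions match categories *C* = {c₁,…,cₙ} (de-duplicated: three
trisomies are one Hyperdiploidy match), the RAG score is the mean weight

&nbsp;&nbsp;&nbsp;&nbsp;RAG = (1/n) Σᵢ w(cᵢ) ∈ [1.0, 3.0],

banded as low [1.0,1.5), low-intermediate [1.5,2.0), high-intermediate
[2.0,2.5) and high [2.5,3.0]. Dual-listed genes resolve by detection route:
cytogenetic evidence hits the chromosomal category, a sequence mutation hits the
functional one (an MMSET point mutation is Epigenetic, not t(4;14)). Synonymous
variants are filtered at VCF parse time. Alongside the score, the ISS stage is
derived from serum β2-microglobulin and albumin, and the ultrahigh-risk flag is
set when ISS stage II/III co-occurs with more than one adverse lesion
(+1q, del(17p), t(4;14), t(14;16), t(14;20)). Results render as a "pizza" plot:
one sector per matched category, sector angle ∝ group weight.

## Worked example

```bash
ragmm score --lesions MM027.lesions.tsv --vcf MM027.vcf \
            --beta2m 4.1 --albumin 3.8 --out report --plot
```

with a lesion table carrying FISH del(17p) and +1q plus karyotype trisomies 3
and 9, and a VCF with a BRAF missense and a KRAS synonymous variant, prints:

```
INFO ragmm: knowledge base version 2014.1 (22 categories)
INFO ragmm: MM027.vcf: 1 mutation(s) kept, 1 synonymous filtered
INFO ragmm: sample MM027: 4 matched categorie(s), score 2.250, band high_intermediate
INFO ragmm: ISS stage II
INFO ragmm: report written to report/MM027.report.json
INFO ragmm: pizza plot written to report/MM027.pizza.svg
```

Four categories matched — Del(17p) and +1q (red, 3.0 each), Proliferation via
BRAF (amber, 2.0), Hyperdiploidy via the two trisomies (green, 1.0) — so the
score is (3+3+2+1)/4 = 2.25, a high-intermediate band. The KRAS synonymous
variant was filtered and contributed nothing. The JSON report additionally
carries `"adverse_count": 2` and `"ultrahigh": true`: ISS stage II together
with both del(17p) and +1q defines the ultrahigh-risk combination.

Other subcommands: `ragmm simulate` (seeded synthetic cohorts with ground-truth
scores, written as the same TSV/VCF/CSV dialects the parsers read),
`ragmm trajectory` (serial samples of one patient, with per-interval score
deltas and newly appearing/lost categories), `ragmm validate-kb` (check an
edited knowledge-base YAML). The same functionality is available as a library
(`ragmm.score_sample`, `ragmm.generate_cohort`, …).

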