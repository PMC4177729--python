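# Default RAG-model knowledge base for multiple myeloma.
# 22 categories: hyperdiploidy, five primary IGH translocations, +1q, seven
# deletions, secondary t(8;14), and seven functional mutation categories.
# Edit a copy of this file and pass it via --kb / load_kb() to re-tier.
version: "2014.1"
provenance: >
  Default multiple-myeloma RAG knowledge base. Category rows, candidate genes
  and event classes transcribed from the published model tables. The
  red/amber/green membership is a RECONSTRUCTION from the model's stated
  tiering rules (adverse prognosis -> red; superior survival -> green;
  neutral or uncharacterised prognostic impact -> amber; t(4;14) demoted to
  amber given bortezomib-era survival): red = Del(17p), t(14;16), t(14;20),
  +1q; green = Hyperdiploidy, t(11;14), t(6;14); amber = all remaining
  categories. Evidence levels/grades are likewise reconstructed metadata
  (grade A throughout; level I for trial-backed FISH lesions, level II for
  other cytogenetic rows, level III for functional categories included on
  functional characterisation and mutational recurrence).
aliases: {}
categories:
  - name: "Hyperdiploidy"
    event_class: initiation_primary
    group: green
    candidate_genes: [CCND1, CCND2, CCND3]
    cytogenetic_pattern:
      kind: trisomy
      loci: ["1", "3", "5", "7", "9", "11", "15", "19", "21"]
    evidence: {level: I, grade: A, note: "Favourable hyperdiploid subtype; trisomies of odd-numbered chromosomes."}
  - name: "t(4;14)"
    event_class: initiation_primary
    group: amber
    candidate_genes: [FGFR3, MMSET]
    cytogenetic_pattern:
      kind: translocation
      loci: ["4", "14"]
    evidence: {level: I, grade: A, note: "Historically high-risk; intermediate-risk with proteasome-inhibitor therapy."}
  - name: "t(6;14)"
    event_class: initiation_primary
    group: green
    candidate_genes: [CCND3]
    cytogenetic_pattern:
      kind: translocation
      loci: ["6", "14"]
    evidence: {level: II, grade: A, note: "Cyclin-D dysregulating IGH translocation; standard risk."}
  - name: "t(11;14)"
    event_class: initiation_primary
    group: green
    candidate_genes: [CCND1]
    cytogenetic_pattern:
      kind: translocation
      loci: ["11", "14"]
    evidence: {level: I, grade: A, note: "CCND1-dysregulating IGH translocation; standard risk."}
  - name: "t(14;16)"
    event_class: initiation_primary
    group: red
    candidate_genes: [c-MAF]
    cytogenetic_pattern:
      kind: translocation
      loci: ["14", "16"]
    evidence: {level: I, grade: A, note: "Adverse MAF-family IGH translocation."}
  - name: "t(14;20)"
    event_class: initiation_primary
    group: red
    candidate_genes: [MAFB]
    cytogenetic_pattern:
      kind: translocation
      loci: ["14", "20"]
    evidence: {level: I, grade: A, note: "Adverse MAF-family IGH translocation."}
  - name: "+1q"
    event_class: progression_secondary
    group: red
    candidate_genes: [CKS1B, ANP32E]
    cytogenetic_pattern:
      kind: gain
      loci: ["1q"]
    evidence: {level: I, grade: A, note: "1q21 gain; adverse per comprehensive FISH-panel multivariate analysis."}
  - name: "Del(1p)"
    event_class: progression_secondary
    group: amber
    candidate_genes: [CDKN2C, FAF1, FAM46C]
    cytogenetic_pattern:
      kind: deletion
      loci: ["1p"]
    evidence: {level: II, grade: A, note: "1p deletion."}
  - name: "Del(11q)"
    event_class: progression_secondary
    group: amber
    candidate_genes: [BIRC2, BIRC3]
    cytogenetic_pattern:
      kind: deletion
      loci: ["11q"]
    evidence: {level: II, grade: A, note: "11q deletion disrupting NF-κB regulators."}
  - name: "Del(12p)"
    event_class: progression_secondary
    group: amber
    candidate_genes: [CD27]
    cytogenetic_pattern:
      kind: deletion
      loci: ["12p"]
    evidence: {level: II, grade: A, note: "12p deletion."}
  - name: "Del(13/13q)"
    event_class: progression_secondary
    group: amber
    candidate_genes: [RB1, DIS3]
    cytogenetic_pattern:
      kind: deletion
      loci: ["13", "13q"]
    evidence: {level: II, grade: A, note: "Monosomy 13 or 13q deletion."}
  - name: "Del(14q)"
    event_class: progression_secondary
    group: amber
    candidate_genes: [TRAF3]
    cytogenetic_pattern:
      kind: deletion
      loci: ["14q"]
    evidence: {level: II, grade: A, note: "14q deletion."}
  - name: "Del(16q)"
    event_class: progression_secondary
    group: amber
    candidate_genes: [CYLD, WWOX]
    cytogenetic_pattern:
      kind: deletion
      loci: ["16q"]
    evidence: {level: II, grade: A, note: "16q deletion."}
  - name: "Del(17p)"
    event_class: progression_secondary
    group: red
    candidate_genes: [TP53]
    cytogenetic_pattern:
      kind: deletion
      loci: ["17p"]
    evidence: {level: I, grade: A, note: "TP53 locus deletion; adverse across treatment settings."}
  - name: "Secondary t(8;14)"
    event_class: progression_secondary
    group: amber
    candidate_genes: [MYC]
    cytogenetic_pattern:
      kind: translocation
      loci: ["8", "14"]
    evidence: {level: II, grade: A, note: "Secondary MYC-IGH rearrangement."}
  - name: "Bone disease"
    event_class: progression_secondary
    group: amber
    candidate_genes: [DKK1, FRZB]
    evidence: {level: III, grade: A, note: "Wnt-pathway inhibitors linked to lytic bone disease; prognostic weight unestablished."}
  - name: "Proliferation"
    event_class: progression_secondary
    group: amber
    candidate_genes: [NRAS, KRAS, BRAF, MYC]
    evidence: {level: III, grade: A, note: "Recurrent MAPK-pathway and MYC mutations."}
  - name: "NF-κB"
    event_class: progression_secondary
    group: amber
    candidate_genes: [TRAF2, TRAF3, CYLD, NFKB1, NFKB2, NIK, TACI, LTBR, BIRC2, BIRC3, WWOX, CD40]
    evidence: {level: III, grade: A, note: "Apoptosis/NF-κB pathway; included on functional characterisation and recurrence."}
  - name: "Differentiation"
    event_class: progression_secondary
    group: amber
    candidate_genes: [XBP1, BLIMP1, IRF4]
    evidence: {level: III, grade: A, note: "Plasma-cell differentiation programme."}
  - name: "DNA repair"
    event_class: progression_secondary
    group: amber
    candidate_genes: [TP53, PARP1]
    evidence: {level: III, grade: A, note: "DNA-damage response."}
  - name: "RNA editing"
    event_class: progression_secondary
    group: amber
    candidate_genes: [DIS3, FAM46C, LRRK2]
    evidence: {level: III, grade: A, note: "RNA processing/editing; recurrently mutated."}
  - name: "Epigenetic"
    event_class: progression_secondary
    group: amber
    candidate_genes: [KDM6A, KDM6B, MLL, MMSET, HOXA9]
    evidence: {level: III, grade: A, note: "Chromatin modifiers; included on functional characterisation and recurrence."}
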