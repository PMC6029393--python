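# Default 19-marker / 24-assay urine DNA-methylation panel for prostate-cancer
# detection: 19 CpG islands associated with 18 genes (the HOXD3 gene carries two
# islands, treated as separate markers), assayed by nested methylation-specific
# qPCR.  Five markers carry two assays, one designed from the forward strand and
# one from the reverse complement (assay ids with an "rc" suffix).
#
# bisulfite_group records which of the two deamination conditions an assay is
# run under (14 min at 70 C or 42 min at 80 C).  It is sample-QC metadata only
# and never enters any score; the grouping below is a placeholder assignment
# (forward-strand assays -> 14min70C, reverse-complement -> 42min80C), as the
# published per-assay grouping is not reproduced here.
name: urine-pca-19
markers:
  - marker_id: ADCY4
    gene: ADCY4
    assays:
      - {assay_id: ADCY4, strand: forward, bisulfite_group: 14min70C}
  - marker_id: AOX1
    gene: AOX1
    assays:
      - {assay_id: AOX1rc, strand: reverse-complement, bisulfite_group: 42min80C}
  - marker_id: APC
    gene: APC
    assays:
      - {assay_id: APC2, strand: forward, bisulfite_group: 14min70C}
  - marker_id: CXCL14
    gene: CXCL14
    assays:
      - {assay_id: CXCL14, strand: forward, bisulfite_group: 14min70C}
      - {assay_id: CXCL14rc, strand: reverse-complement, bisulfite_group: 42min80C}
  - marker_id: EPHX3
    gene: EPHX3
    assays:
      - {assay_id: EPHX3, strand: forward, bisulfite_group: 14min70C}
  - marker_id: GFRA2
    gene: GFRA2
    assays:
      - {assay_id: GFRA2, strand: forward, bisulfite_group: 14min70C}
  - marker_id: GSTP1
    gene: GSTP1
    assays:
      - {assay_id: GSTP1, strand: forward, bisulfite_group: 14min70C}
  - marker_id: HEMK1
    gene: HEMK1
    assays:
      - {assay_id: HEMK1, strand: forward, bisulfite_group: 14min70C}
  - marker_id: HOXA7
    gene: HOXA7
    assays:
      - {assay_id: HOXA7, strand: forward, bisulfite_group: 14min70C}
  - marker_id: HOXB5
    gene: HOXB5
    assays:
      - {assay_id: HOXB5, strand: forward, bisulfite_group: 14min70C}
      - {assay_id: HOXB5rc, strand: reverse-complement, bisulfite_group: 42min80C}
  - marker_id: HOXD10
    gene: HOXD10
    assays:
      - {assay_id: HOXD10, strand: forward, bisulfite_group: 14min70C}
  - marker_id: HOXD3a
    gene: HOXD3
    assays:
      - {assay_id: HOXD3a, strand: forward, bisulfite_group: 14min70C}
  - marker_id: HOXD3b
    gene: HOXD3
    assays:
      - {assay_id: HOXD3b, strand: forward, bisulfite_group: 14min70C}
  - marker_id: HOXD9
    gene: HOXD9
    assays:
      - {assay_id: HOXD9, strand: forward, bisulfite_group: 42min80C}
  - marker_id: KIFC2
    gene: KIFC2
    assays:
      - {assay_id: KIFC2, strand: forward, bisulfite_group: 14min70C}
      - {assay_id: KIFC2rc, strand: reverse-complement, bisulfite_group: 42min80C}
  - marker_id: MOXD1
    gene: MOXD1
    assays:
      - {assay_id: MOXD1, strand: forward, bisulfite_group: 14min70C}
  - marker_id: NEUROG3
    gene: NEUROG3
    assays:
      - {assay_id: NEUROG3, strand: forward, bisulfite_group: 14min70C}
  - marker_id: NODAL
    gene: NODAL
    assays:
      - {assay_id: NODAL, strand: forward, bisulfite_group: 14min70C}
      - {assay_id: NODALrc, strand: reverse-complement, bisulfite_group: 42min80C}
  - marker_id: RASSF5
    gene: RASSF5
    assays:
      - {assay_id: RASSF5, strand: forward, bisulfite_group: 14min70C}
      - {assay_id: RASSF5rc, strand: reverse-complement, bisulfite_group: 42min80C}
# Recovery controls verify that amplifiable DNA survived collection, bisulfite
# conversion and amplification.  NSD1 is an imprinted promoter methylated in all
# DNA (14-min condition); the HOXD9 control detects the unmethylated HOXD9
# promoter copy with degenerate primers (42-min condition).  Control assays are
# QC-only and never enter the 19-marker scores.
controls:
  - {assay_id: NSD1, bisulfite_group: 14min70C}
  - {assay_id: HOXD9ctrl, bisulfite_group: 42min80C}
# Alternate labels seen for the same assays; resolved on ingest.
aliases:
  HEMK1rc: HEMK1
  AOX1: AOX1rc
  APC: APC2
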