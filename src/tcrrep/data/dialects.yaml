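# Column dialects for rearrangement tables. Adding a vendor dialect is a
# config-only change: map the vendor's column names onto the internal fields
# and state the token written for a productive rearrangement.
immunoseq:
  columns:
    nucleotide: cdr3_nt
    aminoAcid: cdr3_aa
    vGeneName: v_gene
    jGeneName: j_gene
    count (templates): templates
    sequenceStatus: productive
  productive_true: "In"
  productive_false: "Out"
  write_order:
    - nucleotide
    - aminoAcid
    - vGeneName
    - jGeneName
    - count (templates)
    - sequenceStatus
airr:
  columns:
    junction: cdr3_nt
    junction_aa: cdr3_aa
    v_call: v_gene
    j_call: j_gene
    duplicate_count: templates
    productive: productive
  productive_true: "T"
  productive_false: "F"
  write_order:
    - junction
    - junction_aa
    - v_call
    - j_call
    - duplicate_count
    - productive
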