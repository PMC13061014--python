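{
  "comment": "Header mapping for the GrandSLAM-style output dialect. Keys are emitted headers (in order); values are native column names.",
  "columns": [
    ["Gene", "gene_id"],
    ["Symbol", "gene_name"],
    ["Readcount", "read_count"],
    ["Conversions", "conversions"],
    ["Coverage", "t_coverage"],
    ["MAP", "ntr_map"],
    ["Mean", "ntr_mean"],
    ["lower", "ntr_q05"],
    ["upper", "ntr_q95"]
  ]
}
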