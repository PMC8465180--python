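{
  "printed_total_n_deg": 2347,
  "column_sum_note": "the per-row n_deg column sums to 2747; the printed grand total is 2347; both are preserved verbatim and never asserted equal"
}
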