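{
  "SUD": "#1f77b4",
  "SZ": "#aec7e8",
  "BD": "#ff7f0e",
  "SRD": "#ffbb78",
  "OMD": "#2ca02c",
  "AND": "#98df8a",
  "OCD": "#d62728",
  "SAD": "#ff9896",
  "SOM": "#9467bd",
  "ED": "#c5b0d5",
  "PD": "#8c564b",
  "ID": "#c49c94",
  "ODD": "#e377c2",
  "ASD": "#f7b6d2",
  "ADHD": "#bcbd22",
  "CD": "#dbdb8d",
  "AD": "#17becf",
  "TD": "#9edae5",
  "OTHER": "#7f7f7f",
  "DEAD": "#000000",
  "EMIGRATED": "#c7c7c7"
}
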