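{
  "description": "Annotated nucleus counts per split of the BBBC038 benchmark collection",
  "splits": {
    "train": 29464,
    "stage1_test": 4152,
    "stage2_test": 3717
  },
  "total": 37333,
  "n_images": 841
}
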