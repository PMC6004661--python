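# Incretin-based antidiabetic drug classes, by normalized generic name.
GLP-1-RAs:
  - dulaglutide
  - exenatide
  - liraglutide
  - lixisenatide
DPP-4-Is:
  - alogliptin
  - anagliptin
  - linagliptin
  - omarigliptin
  - saxagliptin
  - sitagliptin
  - teneligliptin
  - trelagliptin
  - vildagliptin
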