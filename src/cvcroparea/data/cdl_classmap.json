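{
 "_comment": "Convenience CDL class map: field crops (incl. double crops and fallow/idle) -> crop; open water, aquaculture, clouds/no-data, perennial ice and tree crops -> masked; everything else -> non-crop. Override per study.",
 "crop_codes": [
  1,
  2,
  3,
  4,
  5,
  6,
  7,
  8,
  9,
  10,
  11,
  12,
  13,
  14,
  15,
  16,
  17,
  18,
  19,
  20,
  21,
  22,
  23,
  24,
  25,
  26,
  27,
  28,
  29,
  30,
  31,
  32,
  33,
  34,
  35,
  36,
  37,
  38,
  39,
  40,
  41,
  42,
  43,
  44,
  45,
  46,
  47,
  48,
  49,
  50,
  51,
  52,
  53,
  54,
  55,
  56,
  57,
  58,
  59,
  60,
  61,
  205,
  206,
  207,
  208,
  209,
  213,
  214,
  216,
  219,
  221,
  222,
  224,
  225,
  226,
  227,
  228,
  229,
  230,
  231,
  232,
  233,
  234,
  235,
  236,
  237,
  238,
  239,
  240,
  241,
  242,
  243,
  244,
  245,
  246,
  247,
  248,
  249,
  250,
  251,
  252,
  253,
  254
 ],
 "masked_codes": [
  66,
  67,
  68,
  69,
  70,
  71,
  72,
  74,
  75,
  76,
  77,
  81,
  83,
  92,
  111,
  112,
  204,
  210,
  211,
  212,
  215,
  217,
  218,
  220,
  223
 ]
}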