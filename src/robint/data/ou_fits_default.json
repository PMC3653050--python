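{
 "meta": {
  "n_neurons": 100,
  "rho": 0.11,
  "tau_syn": 20.0,
  "dt": 0.5,
  "duration_ms": 500000.0,
  "seed": 20130227
 },
 "rate": [
  9.76,
  14.88,
  17.44,
  18.72,
  19.36,
  20.0,
  21.28,
  22.56,
  25.12,
  30.24,
  40.48
 ],
 "variance": [
  18.047198767293626,
  27.456371791079448,
  31.830316221019405,
  35.28461835509039,
  35.79584530098948,
  37.21972373284458,
  34.95642259824753,
  43.96712341595715,
  46.49787695496346,
  60.39428827107983,
  76.91649738011442
 ],
 "tau": [
  20.489136269884078,
  21.43783208905168,
  20.17792958479615,
  21.662501891335197,
  20.036725117621053,
  20.54443482832759,
  22.436645298031802,
  18.98674146715477,
  20.22897647188827,
  19.788348401389108,
  20.564699462843517
 ]
}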