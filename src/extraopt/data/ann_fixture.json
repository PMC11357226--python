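{
 "config": {
  "n_inputs": 4,
  "n_hidden": 9,
  "n_outputs": 1,
  "learning_rate": 0.1,
  "momentum": 0.7,
  "max_epochs": 20000,
  "patience": 6,
  "split": [
   1.0,
   0.0,
   0.0
  ],
  "seed": 19,
  "hidden_activation": "tanh",
  "output_activation": "identity"
 },
 "w_hidden": [
  [
   0.2891423081989613,
   1.040857064897276,
   -0.10027299381386066,
   -0.43729525214215376,
   -0.9063025334062883,
   0.14273233111789405,
   -0.08116334419478419,
   0.057824133246719575,
   -1.1690859429119695
  ],
  [
   1.446514079846761,
   0.8683917971231585,
   0.13640409410922388,
   0.5446462593727518,
   0.33732859504710144,
   -0.17790601834290498,
   0.4907307962845292,
   -0.17681795982504023,
   0.19919291897806565
  ],
  [
   0.47015700881152983,
   0.05562610874623669,
   -0.46675268014403515,
   -1.6700653094445466,
   0.8513127240893229,
   0.09266618167792946,
   0.3643769502688791,
   0.03596529495225647,
   0.14268441283849576
  ],
  [
   0.4232960600471541,
   -0.8316669976681177,
   -0.015465368374664695,
   1.04336341189701,
   -0.8781017995899909,
   -0.31273385534531967,
   1.0182950761369511,
   -0.06929521851237645,
   -0.06216776295170092
  ]
 ],
 "b_hidden": [
  -0.46851220771051016,
  0.8475867068607941,
  0.20950121477671071,
  -1.1511091549840555,
  -0.6776319363660374,
  0.6558162143486002,
  0.2228471954531894,
  0.2553578995974445,
  0.6454187029044741
 ],
 "w_out": [
  [
   -0.750275074631411
  ],
  [
   0.7977309494712417
  ],
  [
   0.10467006696874114
  ],
  [
   -1.1431602511830625
  ],
  [
   -0.8235194558403863
  ],
  [
   -0.9944009352547691
  ],
  [
   0.8392781138384229
  ],
  [
   -0.3624880281941762
  ],
  [
   0.9703560867010926
  ]
 ],
 "b_out": [
  -1.5069847757596655
 ],
 "input_scaler": {
  "lo": [
   -1.0,
   -1.0,
   -1.0,
   -1.0
  ],
  "hi": [
   1.0,
   1.0,
   1.0,
   1.0
  ]
 },
 "output_scaler": {
  "lo": [
   55.91
  ],
  "hi": [
   125.46
  ]
 }
}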