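# Default five-state Markovian finite-state grammar (synthetic transcription).
# Letter strings are formed by entering at one of the entry transitions and
# walking lettered transitions until an exit state is reached.  This rule
# system is a synthetic reconstruction over the alphabet {X, V, J, T},
# built so that e.g. "XVJ" and "XVXJ" are grammatical while "XVXT" is not,
# and so that 50+ distinct grammatical strings of 2-6 letters exist.
states: [S1, S2, S3, S4, S5]
alphabet: [X, V, J, T]
entries:
  - [S1, X]
  - [S4, T]
transitions:
  - [S1, S2, V]
  - [S1, S3, J]
  - [S2, S1, X]
  - [S2, S3, J]
  - [S2, S4, V]
  - [S3, S4, T]
  - [S3, S5, X]
  - [S4, S4, T]
  - [S4, S5, V]
  - [S5, S3, J]
exits: [S3, S5]
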