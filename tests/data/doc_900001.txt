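The disorder first presents with joint pain in early childhood.

## clinical features
One cohort described chronic joint pain accompanied by night blindness
in most affected individuals.

A later series documented muscle weakness in all patients.

## molecular genetics
Muscle weakness in this section must not be reported because the
section is excluded.

## diagnosis
Diagnosis rests on observing rhythmic  shaking of the hands.
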