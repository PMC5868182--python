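format-version: 1.2

[Term]
id: M:0000000
name: clinical sign

[Term]
id: M:0000001
name: Joint pain
is_a: M:0000000 ! clinical sign

[Term]
id: M:0000002
name: Chronic joint pain
is_a: M:0000001 ! Joint pain

[Term]
id: M:0000003
name: Night blindness
is_a: M:0000000 ! clinical sign

[Term]
id: M:0000004
name: Muscle weakness
is_a: M:0000000 ! clinical sign

[Term]
id: M:0000005
name: Tremor
synonym: "rhythmic shaking" EXACT []
is_a: M:0000000 ! clinical sign

[Term]
id: M:0000006
name: Stiff neck
is_a: M:0000000 ! clinical sign

[Term]
id: M:0000007
name: Nuchal rigidity
synonym: "stiff neck" EXACT []
is_a: M:0000000 ! clinical sign
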