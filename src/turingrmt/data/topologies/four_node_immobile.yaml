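# Four-node extension: two immobile nodes, each closing a negative feedback
# loop on one of the diffusing species (1 -> 3 -| 1 and 2 -> 4 -| 2).
names: [activator, inhibitor, immobile1, immobile2]
adjacency:
- [1, -1, -1, 0]
- [1, -1, 0, -1]
- [1, 0, 0, 0]
- [0, 1, 0, 0]
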