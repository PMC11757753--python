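# Activator-inhibitor core extended with one immobile node in a negative
# feedback loop: node 1 activates node 3, node 3 inhibits node 1.
# Nodes 1 and 2 diffuse; node 3 is immobile.
names: [activator, inhibitor, immobile1]
adjacency:
- [1, -1, -1]
- [1, -1, 0]
- [1, 0, 0]
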