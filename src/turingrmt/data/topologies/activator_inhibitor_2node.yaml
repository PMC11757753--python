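# Gierer-Meinhardt-type activator-inhibitor pair.
# adjacency[i][j] = sign of the edge j -> i (+1 activation, -1 inhibition).
# Node 1 (activator) activates itself and node 2; node 2 (inhibitor)
# inhibits node 1 and itself.  Both nodes diffuse.
names: [activator, inhibitor]
adjacency:
- [1, -1]
- [1, -1]
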