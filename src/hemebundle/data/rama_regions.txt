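# Simplified Ramachandran region grid, 10 deg x 10 deg.
# Rows: phi from -180 (top) to +170; columns: psi from -180 (left) to +170.
# F = favored, A = additionally allowed, G = generously allowed, D = disallowed.
FFFAGDDDDGGGGGGGGGGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAAAAAAAAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
FFFAGDDDDGAFFFFFFAGDDDDDDGAFFFFFFFFF
AAAAGDDDDGAFFFFFFAGDDDDDDGAAAAAAAAAA
GGGGGDDDDGAAAAAAAAGDDDDDDGGGGGGGGGGG
DDDDDDDDDGGGGGGGGGGDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDGGGGGGGGGGGDDDDDDDD
DDDDDDDDDDDDDDDDDGAAAAAAAAAGDDDDDDDD
DDDDDDDDDDDDDDDDDGAFFFFFFFAGDDDDDDDD
DDDDDDDDDDDDDDDDDGAFFFFFFFAGDDDDDDDD
DDDDDDDDDDDDDDDDDGAFFFFFFFAGDDDDDDDD
DDDDDDDDDDDDDDDDDGAFFFFFFFAGDDDDDDDD
DDDDDDDDDDDDDDDDDGAAAAAAAAAGDDDDDDDD
DDDDDDDDDDDDDDDDDGGGGGGGGGGGDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
DDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDDD
GGGGGDDDDDDDDDDDDDDDDDDDDGGGGGGGGGGG
AAAAGDDDDDDDDDDDDDDDDDDDDGAAAAAAAAAA
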