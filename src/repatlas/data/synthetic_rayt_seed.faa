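>rayt_seed_synthetic REP-associated tyrosine transposase, synthetic stand-in query (HxH + catalytic Y motifs)
MNYSYRYRLRPGEQFEAALDEWLPLFNRACAWVAEHRGKSLGQVGGIAVSQALLTSETKG
QLPSAFAGDVIRQAFVDRAQLAHTHIVRGRSSDAPLQGYDLALTLRSEAWLDEQGGHPRF
DLVSLRPVEWQQGEHIWQLSLSREDGSRQQIAVPFAEYLGLPESGSLKQAQLVRQADGSW
FVHIQIQREVPQAVAERNGAVGVDLGIKELATLSTGEKIANPKHYRTLEKKLARAQRVLS
RRQKGSANWHKQRVKVARLHLRIADSRRDWQHKLSTRLIRENQTIVLEDLRVANMVKNHH
LARSIADAGWGEFVRQLEYKAAWYGRELIKVDRWFPSSKRCGNCGHIVEKLPLNVREWDC
PNCGAHHDRDGNAAINILAAGHAVSACGAGVRPQRESSRTARKLAV
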