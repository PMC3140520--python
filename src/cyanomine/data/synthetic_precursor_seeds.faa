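>NHLP_a NHLP 15
MKELEQNEINEIEGGKIFDAPFRDYKQDGKNHITSPKQVMDPLEYPGLPGVHISIRTMFI
>NHLP_b NHLP 15
MRELETEEIEYVQGGTIFVAPFRDYKQAGKNSIVSNFQVMYPLEYPGLPIVWISIRTMFI
>NHLP_c NHLP 15
MRELTECEIDEVWGGHIFNAPIRDWKQAGKNSITSNDQVMYPNEYPGLPGDWIAIRMMFG
>N11P_a N11P 15
MKELVTLELYEISGGVFECINRAMEMMDRGFTQGWQCTICMKPNQQGERFSSV
>N11P_b N11P 15
MRELDERELWDVIGGVFECINRAMYMMDLGFGQGCVCTICMKPNQQRERFSSQ
>N11P_c N11P 15
MKELDPDEIVDIWGGVFECINRAMYMMDRGFTQGCQCTICMKPNQQRERFSSQ
>HETP_a HETP 24
MRYKIRDLVYLESAKRDRLRTRGGCCQDSFFKYIMFNDNDPICFAEVALEKHTC
>HETP_b HETP 24
MRYKIKDLRYLEKCICKQRDYKGGKCQSSFFCSIMFNDNDPSYVPFPALEKHTC
>HETP_c HETP 24
MQKKIHDLCYLERKCNDRRKRVGGCCQVSFFCYIMFNDNDPSYVPFVALEKHTC
>DUF37_a DUF37 15
MRELGKQEIFHVTGGWCTCTKPMDQKISLMKCGSAGVILT
>DUF37_b DUF37 15
MKELCHKELTNIPGGWCTHTKWMDQKISLMKCGSAGVMLT
>DUF37_c DUF37 15
MRELRKFELQWVHGGWCTCTKWMDQKISLMNCGSAGVMLT
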