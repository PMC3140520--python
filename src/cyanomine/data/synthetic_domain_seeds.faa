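>c39_peptidase_1 C39_PEPTIDASE
MMRQGVQPISDYCGSSTRGAGYNRAMSHRHCKFWWQFPLGREPVCKCSVDIQTLTEPMCQ
RHSYLEMNSWKYDHHHKMFRETSARAGSRKICQACADQGTMHYHREKSCYFQKWIYHQCA
KNPYMDQETM
>abc_tm_region_1 ABC_TM_REGION
MTPRGTTLRNQQEGIRDILWDGTMDFLRMWFKWKVVSVQMTEYNHNHVQPQNNVTEMSIW
EYIFQQLRENRNWSEAPAEYPWYPTKPCKQGWWWTGLTETVRHCLAETYWWGQKYIYWIS
AYMTNVWPHLPDLSEMKEKITNHRENQLPCTHVCKPKKQQGEHGDECNFGMFLIWVDYNT
CHWINPHINTWFMLNAKPSHSSIWKEMSQCPCQYLSPKHEHKLDQKYSTNCLKLNKVVIK
HIRGDLNNHFAEHFKINDNFWMWKIIAHIE
>atp_binding_cassette_1 ATP_BINDING_CASSETTE
MCGPGAMNTMCAMEPKLIPIYDTTTVMCEEWNNICEVFIMATWFSESCTVKVMNPLTYFI
MRFPIYHLYRPPKDTKFFMVPMTKQLQFHCCGKPLGCQQIGETYGGHSVKFSRSLINDWF
LWGNTSPVNYQKAPKDVYLNFMWGINALYTVKCNPLAYDGYDPYHASLWVPAVRENVQCP
TIPKQKAGTHMEKDACLWWTLGGQVATNQCDTYCDCPWSY
>cap_ed_1 CAP_ED
MLAEQMAWMTWMINLYWTSIFIIMPRNNGYFSMVWGNIFPRNWHGQRHFQEELKKKAHAR
ELLYRHLAHKWKPHFTQRVLWSKAHTNECCVGLTFSKPGSAQNICAYQIVIFKCYAECEP
WSRILIGTITHLEWTKSLADISQLIRYHYASIRKPMLMAQPTFGHSTWGYELFGEHHLQT
NCSLMIWNDLPMTFMFPMRELQEHDMDPWPNMDEAEKEWNYLFNWVEHGDTLSWEIDVPK
DLEESKALAFDSNNDRICQKDYATCEAWMCVFMGFIIGEKITHNLHLMHD
>type_i_hlyd_1 TYPE_I_HLYD
MSRIVAVSLVFKLYQVCKSCKCVCGISAPWWINRYICKEYLWGIMARGMASPHVINQWSV
LKRNNQHDFMCDAFLGTYWRWGTPKKFKPMDRGMRCRVFHGIVIECMPVPMEIYFGRWAL
FMFDYIHVPQHGDALLKAVVCIPYTKPQDNLNLLDKLWTEERFNDKVKGISSYKKGCLAQ
PCAMSTFTGAKKVCMHTWYLQKVEWTMNHQCLVRHMFKPPSCYVGVATGGMAGAPMMVYL
DTNGHDNWDAAQCKFWHNYFVIDNRIVYRFPFKCSKEEYLLTFERHAGEEHNYAMAWEFN
>rotamase_1 ROTAMASE
MMWPSMHMRCMFKNCIWMSHHCVKDPGSDVRETVQWYQKVSGSKAHIIRCVKQAAVVRFC
DQSMDSMQEYFKSFYYCPITHANVDSMWAFPHLFKTPKRPMIPGWCDWRWIAMCTSWEFR
HMGCYTYYPRPPEKNTSGYMGASQVCREMQ
>lanm_1 LANM
MVRLETRRWARFEWFSVDCMVTMGYHALAMDFSEEMHDVEHSISPVENRHAWDWQACMIW
YICCARCMDPCLPDNCPGDKRWICCRLYQRNEWSEEIQVFTKMDCGLSADYFLGDMQMLW
YQQKLEWFVFRNSQDLFPHNEECMDRAVSIDRSMLHDIACGNVWAYRTGNFPDWEKNEGD
QFFRDGFGPWPHSCRASWIDWKFKDCKHCPSKDEARDSQDVSMWFGAEALICHESENYPY
QAIPHNMPNNAEWPEGWWGIHIEWQMMATECGRLRITFVSACFHMGYFWQTDDMARQQWR
VAQKPKEGCYQNMSSTRLQSVTCRKHWWFHGLSRQMSMKIHLPDFMSPICTESNIYQVGD
KNIHTDGQFSCLIFACFNFPGTDQAPAMIFQMEAFGFIPSEPMGKIHWENSNVDISKSIK
>s8_peptidase_1 S8_PEPTIDASE
MYARMDSNSSWDHANNIFQCSDYRQSRPCEADKRGHDYQKWRPTTCMTNGMSWEMPMVTS
KNKTKKNVKLVWAMFCRMHGSQIMVWISLFKMAGWNVWQWGGEGHGPETSECCHTTKASK
NFTISREYFSSLIVDHENIHCHSLGMMHYEENMWDQETWQGELSYVQCQCTYRDGWICWE
LFRPLQATQADYQSNFNNKEFNYVVQWMDGAIVAEWDYQEGRHKESGRYFVEERRIAVCV
RCVSVYVRSMGSASFHNQSQSVDLTSHGALCRSFWIYTWAYPGDRISPFQSCCYNPHSAM
>m16_peptidase_1 M16_PEPTIDASE
MGDGSDVKSQIGETYLPGPKPEGYKPYKDAMILPLETQFRCGDRFHGCRMQDSSKEKFSR
CEMRASFKIPAGSCPSTHSDKHAGWVYQTYAIMAMALHCDDNHDMHLRNVFHSHVQYLAK
ACRSYAHCFNTPFEKPIQRMFQMPWQCDYAEYITHALDQGYYWLVVMNFNFHWAYLPYQQ
KCVCNTSEHQFTSFAYAMMLRNEEEMWDMLWMYMSVQHSRYYKFPKMFGFLWRQQNFYWQ
YNLMKGESIECSKPEIEQQYIRTEPGHDITDHVKKEGNACMCAINYILYYWRQPESHMCP
>duf37_1 DUF37
MMRFTTFLWAFHDKINNVAQRHHTSPPNQKIEDWPLCADIWEFCASGAPMIGVLENDFLN
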