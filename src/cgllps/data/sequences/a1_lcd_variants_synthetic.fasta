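>WT+NLS
GSMASASSSQRGRSGSGNFGGGRGGGFGGNDNFGRGGNFSGRGGFGGSRGGGGYGGSGDG
YNGFGNDGGYGGGGPGYSGGSRGYGSGGQGYGNQGSGFGGFGGSGSYDSFNNGGGGGFGG
GSGSNFGGGGSFNDYGN
>allF
GSMASASSSQRGRSGSGNFGGGRGGGFGGNDNFGRGGNFSGRGGFGGSRGGGGFGGSGDG
FNGFGNDGGFGGGGPGFSGGSRGFGSGGQGFGNQGSGFGGFGGSGSFDSFNNGGGGGFGG
GSGSNFGGGGSFNDYGN
>allY
GSMASASSSQRGRSGSGNYGGGRGGGYGGNDNYGRGGNYSGRGGYGGSRGGGGYGGSGDG
YNGYGNDGGYGGGGPGYSGGSRGYGSGGQGYGNQGSGYGGYGGSGSYDSYNNGGGGGYGG
GSGSNYGGGGSYNDYGN
>allW
GSMASASSSQRGRSGSGNWGGGRGGGWGGNDNWGRGGNWSGRGGWGGSRGGGGWGGSGDG
WNGWGNDGGWGGGGPGWSGGSRGWGSGGQGWGNQGSGWGGWGGSGSWDSWNNGGGGGWGG
GSGSNWGGGGSWNDYGN
>YtoW
GSMASASSSQRGRSGSGNFGGGRGGGFGGNDNFGRGGNFSGRGGFGGSRGGGGWGGSGDG
WNGFGNDGGWGGGGPGWSGGSRGWGSGGQGWGNQGSGFGGFGGSGSWDSFNNGGGGGFGG
GSGSNFGGGGSFNDYGN
>FtoW
GSMASASSSQRGRSGSGNWGGGRGGGWGGNDNWGRGGNWSGRGGWGGSRGGGGYGGSGDG
YNGWGNDGGYGGGGPGYSGGSRGYGSGGQGYGNQGSGWGGWGGSGSYDSWNNGGGGGWGG
GSGSNWGGGGSWNDYGN
>W-
GSMASASSSQRGRSGSGNWGGGRGGGGGGNDNWGRGGNWSGRGGGGGSRGGGGWGGSGDG
WNGGGNDGGWGGGGPGWSGGSRGGGSGGQGWGNQGSGWGGGGGSGSWDSWNNGGGGGGGG
GSGSNWGGGGSWNDYGN
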