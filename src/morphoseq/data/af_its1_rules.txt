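# Diagnostic ITS1 markers for the Anastrepha fraterculus complex sequence
# types, on the canonical 669-column alignment frame. The 5' interrupted
# poly(A) region (columns 1-109) is too variable to align reliably and is
# excluded from all marker matching.
#
# SNP residues are placeholders consistent with the bundled synthetic
# exemplar set: published descriptions give the diagnostic positions but not
# the residues, so this table is editable data, not ground truth. Two
# published coordinates collide across types when forced onto one shared
# column frame; those markers are shifted to the nearest free columns and
# flagged inline.

alignment_length = 669
exclude = 1-109

[TI]
insertion    TCACATATA 301 310 required
repeat       ATT*3-3   368 376 required
substitution G         353 353 required
substitution C         403 403 required
substitution G         417 417 required

[TIa] parent=TI
insertion    ATT       580 582 required

[TIb] parent=TI
insertion    CCC       129 131 required
insertion    CCCC      177 180 required

[TIc] parent=TI
insertion    G         125 125 required
insertion    G         232 232 required
insertion    A         668 668 required

[TId] parent=TI
insertion    TAT       359 361 required

[TIe] parent=TI
repeat       T*9-9     291 298 required
insertion    CCCC      302 305 required
insertion    CACA      493 496 required
insertion    GGAAA     602 606 required

[TII]
reduction    TTT<TATAT 110 114 required
insertion    TGGGTGG   211 217 required
repeat       T*7-7     243 249 required
repeat       ATT*4-5   565 579 required
substitution T         137 137 required
substitution A         190 190 required
substitution T         410 410 required
substitution G         669 669 required

[TIIa] parent=TII
insertion    AAC       143 145 required
insertion    GGGGG     227 230 required
insertion    TTATAAA   497 503 required

[TIIb] parent=TII
insertion    GAG       478 480 required
insertion    AAA       501 503 required
insertion    TG        540 541 required

[TIIc] parent=TII
insertion    AAAAAA    560 565 required
# GGGGA is published at 353-356 but column 353 is the first diagnostic SNP
# column of type TI on this frame; placed at the adjacent free columns.
insertion    GGGGA     354 358 required

[TIIIA]
insertion    CAATATATA 380 388 required
insertion    A         391 391 required
insertion    AT        419 420 required
insertion    A         569 569 required

[TIV]
substitution T         119 119 required
substitution G         151 151 required
substitution C         343 343 required
substitution A         421 421 required
repeat       ATT*2-3   539 541 required

[TIVa] parent=TIV
# Single-base additions; the published account says G, T or A without
# assigning residues to columns, so the residues below are placeholders.
# Columns 137 and 243 collide with type TII's SNP column and T homopolymer
# on this frame; those two sit at the adjacent free columns 138 and 250.
insertion    G         125 125 required
insertion    T         131 131 required
insertion    A         138 138 required
insertion    T         139 139 required
insertion    G         162 162 required
insertion    A         166 166 required
insertion    T         232 232 required
insertion    G         250 250 required
insertion    A         445 445 required
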