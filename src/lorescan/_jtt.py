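"""Empirical amino-acid substitution model constants.

The JTT (Jones-Taylor-Thornton 1992) exchangeability table and stationary
frequencies, in the standard one-letter order ARNDCQEGHILKMFPSTWYV.
``JTT_EXCH`` holds the lower triangle column-wise (190 values), as the
table is conventionally distributed.
"""

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

JTT_EXCH = (
    58, 54, 81, 56, 57, 105, 179, 27, 36, 30,
    35, 54, 15, 194, 378, 475, 9, 11, 298, 45,
    16, 113, 310, 29, 137, 328, 22, 38, 646, 44,
    5, 74, 101, 64, 126, 20, 17, 528, 34, 86,
    58, 81, 391, 47, 12, 263, 30, 10, 15, 503,
    232, 8, 70, 16, 10, 49, 767, 130, 112, 11,
    7, 26, 15, 4, 15, 59, 38, 4, 46, 31,
    9, 5, 59, 69, 17, 23, 7, 31, 78, 14,
    223, 42, 115, 209, 62, 323, 26, 597, 9, 72,
    292, 43, 4, 164, 53, 51, 18, 24, 20, 119,
    26, 12, 9, 181, 18, 5, 18, 30, 32, 10,
    7, 45, 23, 6, 6, 27, 14, 5, 24, 201,
    33, 55, 8, 47, 16, 56, 45, 33, 40, 115,
    73, 46, 8, 573, 11, 229, 21, 479, 89, 10,
    40, 245, 9, 32, 961, 14, 388, 248, 102, 59,
    25, 52, 24, 180, 65, 4, 21, 47, 103, 10,
    8, 14, 43, 16, 29, 226, 24, 18, 323, 17,
    92, 12, 53, 536, 62, 285, 118, 6, 10, 23,
    477, 35, 63, 38, 12, 21, 112, 71, 25, 16,
)

JTT_FREQS = (
    0.0767479233, 0.0516909483, 0.0426449574, 0.0515439485,
    0.0198029802, 0.0407519592, 0.0618299382, 0.0731519268,
    0.0229439771, 0.0537609462, 0.0919039081, 0.0586759413,
    0.0238259762, 0.0401259599, 0.0509009491, 0.0687649312,
    0.0585649414, 0.0142609857, 0.0321019679, 0.0660049340,
)
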