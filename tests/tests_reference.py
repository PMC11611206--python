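"""Frozen reference statistics computed independently with R 4.3.

kruskal.test, wilcox.test (exact for these group sizes) and
p.adjust(method="BH") were run once on the fixed vectors below; the values
are frozen here as the conformance oracle.
"""

R_REFERENCE = {
    "vectors": [
        [1.2, 3.4, 2.2, 5.1, 4.0, 2.8],
        [2.5, 6.1, 4.4, 7.0, 5.5, 3.9],
        [8.2, 9.1, 7.7, 10.3, 9.9, 8.8],
    ],
    "kw_H": 12.783625731,
    "kw_p": 0.00167521650474,
    "raw": {("a", "b"): 0.0930735930736,
            ("a", "c"): 0.0021645021645,
            ("b", "c"): 0.0021645021645},
    "bh": {("a", "b"): 0.0930735930736,
           ("a", "c"): 0.00324675324675,
           ("b", "c"): 0.00324675324675},
}
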