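"""Published DREAM4 size-10 challenge results for 14 inference methods.

``PVALUES`` holds, per method, the five (p_aupr, p_auroc) pairs reported
for the five benchmark sub-networks; ``SCORES`` the corresponding printed
per-network scores and total score (3 significant figures).  These are
published benchmark numbers used as test inputs and expectations.
"""

PVALUES = {
    "BMALR":   [(3.20e-28, 3.30e-15), (3.10e-34, 2.10e-22), (3.52e-47, 8.40e-32), (4.21e-41, 4.36e-30), (3.20e-43, 3.67e-33)],
    "GINIE3":  [(3.40e-36, 3.20e-19), (8.40e-21, 2.10e-16), (2.76e-54, 8.70e-34), (2.73e-34, 5.42e-28), (7.41e-37, 3.79e-29)],
    "MRNET":   [(2.31e-11, 1.98e-09), (6.23e-22, 6.11e-19), (4.54e-33, 4.21e-22), (3.46e-30, 5.02e-25), (2.73e-28, 9.93e-19)],
    "ARACNE":  [(6.32e-21, 4.11e-20), (1.25e-22, 1.23e-20), (5.03e-37, 4.05e-25), (5.99e-32, 8.15e-27), (5.31e-37, 7.22e-28)],
    "BGRMI":   [(4.10e-37, 2.50e-21), (6.33e-28, 5.43e-21), (5.23e-39, 5.86e-25), (4.51e-48, 6.31e-34), (4.46e-33, 4.52e-20)],
    "CLR":     [(4.50e-31, 3.20e-18), (2.32e-24, 4.52e-18), (5.72e-55, 6.85e-36), (3.11e-31, 4.26e-27), (3.72e-36, 5.31e-28)],
    "G1DBN":   [(8.24e-10, 8.23e-06), (1.35e-15, 2.23e-15), (3.43e-36, 1.10e-25), (1.27e-31, 4.32e-26), (7.02e-27, 8.76e-18)],
    "NARROMI": [(9.13e-20, 5.42e-18), (1.76e-23, 4.09e-20), (1.32e-40, 7.63e-28), (2.21e-37, 5.72e-27), (3.25e-40, 4.81e-31)],
    "TIGRESS": [(4.30e-22, 1.27e-20), (7.18e-32, 3.56e-20), (3.86e-38, 1.65e-32), (4.20e-43, 3.28e-29), (7.26e-42, 5.68e-33)],
    "GENIRF":  [(3.31e-29, 3.51e-18), (5.41e-35, 2.32e-23), (2.60e-48, 4.27e-31), (3.17e-42, 4.82e-32), (2.62e-44, 2.46e-32)],
    "MIBNI":   [(6.51e-23, 3.19e-22), (3.18e-27, 4.31e-21), (4.27e-41, 2.82e-28), (2.21e-36, 3.17e-28), (1.93e-37, 3.37e-30)],
    "FBISC":   [(1.41e-27, 1.60e-17), (6.31e-36, 4.12e-19), (2.43e-37, 4.22e-21), (1.81e-32, 6.32e-23), (4.81e-36, 2.17e-27)],
    "CMI2NI":  [(1.28e-10, 1.58e-17), (2.61e-08, 3.62e-09), (5.09e-22, 8.09e-18), (2.44e-11, 2.21e-12), (2.55e-12, 3.08e-16)],
    "KFLR":    [(1.63e-33, 1.21e-27), (7.43e-46, 4.12e-32), (4.43e-58, 3.22e-39), (2.81e-53, 7.63e-35), (3.61e-51, 1.35e-37)],
}

# per-network scores NET1..NET5 followed by the total score
SCORES = {
    "BMALR":   [21.0, 27.6, 38.8, 34.9, 37.5, 160],
    "GINIE3":  [27.0, 17.9, 43.3, 30.4, 32.3, 151],
    "MRNET":   [9.67, 19.7, 26.9, 26.9, 22.8, 106],
    "ARACNE":  [19.8, 20.9, 30.3, 28.7, 31.7, 131],
    "BGRMI":   [28.5, 23.7, 31.3, 40.3, 25.8, 150],
    "CLR":     [23.9, 20.5, 44.7, 28.4, 31.4, 149],
    "G1DBN":   [7.08, 14.8, 30.2, 28.1, 21.6, 102],
    "NARROMI": [18.2, 21.1, 33.5, 31.4, 34.9, 139],
    "TIGRESS": [20.6, 25.3, 34.6, 35.4, 36.7, 153],
    "GENIRF":  [23.0, 28.5, 39.0, 36.4, 37.6, 164],
    "MIBNI":   [21.8, 23.4, 34.0, 31.6, 33.1, 144],
    "FBISC":   [21.8, 26.8, 28.5, 27.0, 31.0, 135],
    "CMI2NI":  [13.3, 8.01, 19.2, 11.1, 13.6, 65.2],
    "KFLR":    [29.9, 38.3, 47.9, 43.3, 43.7, 203],
}


def sig3(x: float) -> float:
    """Round to 3 significant figures."""
    return float(f"{x:.3g}")
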