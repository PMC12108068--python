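"""Nearest-neighbor duplex melting temperature for capture probes.

Uses the unified nearest-neighbor parameter set of Allawi & SantaLucia
(Biochemistry 1997) with the SantaLucia (1998) entropic salt correction:

    Tm = 1000 * dH / (dS + 0.368 * (N-1) * ln[Na+] + R * ln(C_T/x)) - 273.15

with dH in kcal/mol, dS in cal/(mol*K), R = 1.987 cal/(mol*K), and
C_T/x the effective oligo concentration (x = 4 for non-self-complementary
duplexes with the probe in excess over target; we model the probe
concentration directly, so k = C_probe). Defaults: 50 mM monovalent salt,
250 pM oligo. The calculation is vectorized over batches of equal-length
probes, which makes whole-genome candidate scoring cheap.

Duplex symmetry holds by construction: a sequence and its reverse
complement describe the same duplex and get identical Tm.
"""

from __future__ import annotations

import math

import numpy as np

from . import seq as sequtil

R_GAS = 1.987  # cal / (mol K)

# Unified NN parameters: dinucleotide (5'->3' top strand) -> (dH kcal/mol,
# dS cal/mol/K). Complementary stacks share parameters.
_NN = {
    "AA": (-7.9, -22.2), "TT": (-7.9, -22.2),
    "AT": (-7.2, -20.4),
    "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "TG": (-8.5, -22.7),
    "GT": (-8.4, -22.4), "AC": (-8.4, -22.4),
    "CT": (-7.8, -21.0), "AG": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "TC": (-8.2, -22.2),
    "CG": (-10.6, -27.2),
    "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9), "CC": (-8.0, -19.9),
}
_INIT_AT = (2.3, 4.1)
_INIT_GC = (0.1, -2.8)

# 4x4 lookup tables indexed by (first base code, second base code)
_DH = np.zeros((4, 4))
_DS = np.zeros((4, 4))
for _d, (_h, _s) in _NN.items():
    _DH[sequtil.CODE[_d[0]], sequtil.CODE[_d[1]]] = _h
    _DS[sequtil.CODE[_d[0]], sequtil.CODE[_d[1]]] = _s

_END_DH = np.array([_INIT_AT[0], _INIT_GC[0], _INIT_GC[0], _INIT_AT[0]])
_END_DS = np.array([_INIT_AT[1], _INIT_GC[1], _INIT_GC[1], _INIT_AT[1]])


def melting_temperatures(
    probes: np.ndarray, salt_mM: float = 50.0, oligo_nM: float = 0.25
) -> np.ndarray:
    """Tm (degC) for a (n_probes, length) uint8 code matrix; N is rejected."""
    probes = np.atleast_2d(np.asarray(probes, dtype=np.uint8))
    if probes.shape[1] < 2:
        raise ValueError("probes must be at least 2 bases long")
    if (probes >= 4).any():
        raise ValueError("Tm is undefined for sequences containing N")
    dh = _DH[probes[:, :-1], probes[:, 1:]].sum(axis=1)
    ds = _DS[probes[:, :-1], probes[:, 1:]].sum(axis=1)
    dh += _END_DH[probes[:, 0]] + _END_DH[probes[:, -1]]
    ds += _END_DS[probes[:, 0]] + _END_DS[probes[:, -1]]
    n = probes.shape[1]
    # self-complementary duplexes: symmetry entropy penalty, no 1/4 dilution
    selfcomp = (probes == (3 - probes[:, ::-1])).all(axis=1)
    ds = ds - 1.4 * selfcomp
    ds_salt = ds + 0.368 * (n - 1) * math.log(salt_mM / 1000.0)
    k = oligo_nM * 1e-9  # probe in excess: effective concentration = C_probe
    return 1000.0 * dh / (ds_salt + R_GAS * math.log(k)) - 273.15


def melting_temperature(
    seq: str, salt_mM: float = 50.0, oligo_nM: float = 0.25
) -> float:
    """Tm (degC) of a single fully specified sequence."""
    codes = sequtil.encode(sequtil.normalize(seq))
    return float(melting_temperatures(codes[None, :], salt_mM, oligo_nM)[0])
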