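"""Finite-difference stress oracle shared by the test modules.

Computes the Cauchy stress as the central finite-difference gradient of the
strain-energy density with respect to F (first Piola-Kirchhoff), pushed
forward and pressure-corrected with the same traction-free direction as the
implementation under test.  Kept independent of the analytic stress path.
"""

import numpy as np

from v2g import constitutive as cst


def _energy_of_F(material, F, fiber):
    """Energy at a (possibly non-unimodular) F, bypassing the det-F guard."""
    st = cst.DeformationState.__new__(cst.DeformationState)
    object.__setattr__(st, "F", F)
    object.__setattr__(st, "fiber_dir", np.asarray(fiber, float))
    C = F.T @ F
    object.__setattr__(st, "C", C)
    object.__setattr__(st, "E", (C - np.eye(3)) / 2.0)
    return cst.energy(material, st)


def fd_cauchy_stress(material, F, fiber, traction_free_dir, h=1e-6):
    P = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            Fp, Fm = F.copy(), F.copy()
            Fp[i, j] += h
            Fm[i, j] -= h
            P[i, j] = (_energy_of_F(material, Fp, fiber)
                       - _energy_of_F(material, Fm, fiber)) / (2 * h)
    sig = P @ F.T / np.linalg.det(F)
    sig = 0.5 * (sig + sig.T)
    n = np.asarray(traction_free_dir, float)
    n = n / np.linalg.norm(n)
    return sig - (n @ sig @ n) * np.eye(3)
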