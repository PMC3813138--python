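"""The two published HDM2-inhibition QSAR equations, coefficients as printed.

These fixed models exist for comparison and for evaluating the published
equations on arbitrary descriptor rows; the package's reference models are
the OLS refits of the packaged tables (see :func:`refit_equation_1` /
:func:`refit_equation_2`), because the printed coefficients are rounded —
and, in the 11-descriptor equation, the BELp6 coefficient as printed is
grossly inconsistent with the published per-ligand predictions.
"""

from __future__ import annotations

from .datasets import (
    TABLE2_DESCRIPTORS,
    TABLE3_DESCRIPTORS,
    DescriptorTable,
    load_table2,
    load_table3,
)
from .regression import FitStats, LinearModel, fit_ols

#: 8-descriptor equation on the commercial-software descriptor set.
EQUATION_1 = LinearModel(
    intercept=14.568,
    coefficients={
        "LogD": 0.388,
        "Num_RotatableBonds": -0.166,
        "Num_StereoAtoms": -0.670,
        "V_DIST_equ": 0.00278,
        "CHI_1": -1.446,
        "Dipole_X": -0.0471,
        "Shadow_Xlength": 0.230,
        "Shadow_XZ": -0.0328,
    },
    provenance="fixed",
)

#: 11-descriptor equation on the E-Dragon descriptor set, as printed.
#: Caution: evaluating these printed coefficients does not reproduce the
#: published predicted column (see module docstring); prefer the refit.
EQUATION_2 = LinearModel(
    intercept=-12.276,
    coefficients={
        "IDE": 7.858,
        "MATS7v": -4.855,
        "DP09": -1.198,
        "Mor14m": -0.448,
        "Mor30p": 1.481,
        "G2e": -25.917,
        "E2e": 1.678,
        "Tp": 0.319,
        "R5u": 61.575,
        "BELp6": -61.64,
        "SeaC2C3aa": 0.272,
    },
    provenance="fixed",
)


def refit_equation_1(
    table: DescriptorTable | None = None,
) -> tuple[LinearModel, FitStats]:
    """OLS refit of the 8-descriptor model on the packaged table."""
    return fit_ols(table or load_table2(), TABLE2_DESCRIPTORS)


def refit_equation_2(
    table: DescriptorTable | None = None,
) -> tuple[LinearModel, FitStats]:
    """OLS refit of the 11-descriptor model on the packaged table."""
    return fit_ols(table or load_table3(), TABLE3_DESCRIPTORS)
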