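"""Published reference inputs used by the worked examples.

Two small printed tables accompany the German product-landscape study
this package's workflow is designed for: the ten best-selling
co-formulants (annual sales, 2021) and the HepaRG cytotoxicity EC50s of
three formulated products, their active substances (AS), co-formulants
and combinations.  They are inputs for examples and cross-checks — the
underlying composition landscape is confidential and is emulated by
:mod:`mixtriage.synthetic` instead.

Abbreviations: Pro prothioconazole, Teb tebuconazole, Pen pendimethalin,
Fluf flufenacet (AS); NOP 1-octyl-2-pyrrolidone, BP
1-butylpyrrolidin-2-one, SN solvent naphtha, NDA N,N-dimethyldecanamide
(co-formulants).
"""

from __future__ import annotations

#: (CAS, name, annual sales in tonnes) — ten best-selling co-formulants.
TOP10_COFORMULANT_SALES_TONNES: tuple[tuple[str, str, float], ...] = (
    ("7732-18-5", "Water", 22962.0),
    ("130498-22-5", "Wheat flour", 3580.0),
    ("14433-76-2", "N,N-Dimethyldecan-1-amide", 3160.0),
    ("64742-94-5", "Solvent naphtha (petroleum), heavy arom. (C9-C16)", 1819.0),
    ("1189173-42-9", "Hydrocarbons, C10, aromatics, <1% naphthalene", 1222.0),
    ("57-55-6", "Propane-1,2-diol", 1078.0),
    ("61791-12-6", "Castor oil, ethoxylated", 974.0),
    ("85586-25-0", "Fatty acids, rape-oil, Me esters", 787.0),
    ("186817-80-1", "Propanoic acid, 2-hydroxy-, 2-ethylhexyl ester, (2S)-", 723.0),
    ("7783-20-2", "Ammonium sulphate", 508.0),
)

#: EC50 (mg/L) from HepaRG viability after 24 h, best-fit non-linear
#: dose-response curves; keyed by treatment label.
HEPARG_EC50_MG_L: dict[str, float] = {
    "Product 4": 22.97,
    "Pro + NOP + BP": 41.11,
    "Pro": 46.31,
    "NOP": 114.9,
    "BP": 1427.0,
    "Product 5": 28.99,
    "Pen + Fluf + SN": 69.98,
    "Pen + Fluf": 131.7,
    "SN": 399.4,
    "Product 6": 9.14,
    "Teb + Pro + NDA": 12.16,
    "Teb + Pro": 45.84,
    "NDA": 79.8,
}

#: IC50 (mg/L) of NDA on recombinant CYP2C19 (4PL fit).
NDA_CYP2C19_IC50_MG_L: float = 0.808


def ec50_shift_ratio(
    baseline_label: str = "Teb + Pro",
    mixture_label: str = "Teb + Pro + NDA",
    table: dict[str, float] | None = None,
) -> float:
    """Fold reduction in EC50 when a co-formulant joins an AS mixture.

    Default labels quantify the potency shift caused by adding NDA to the
    tebuconazole + prothioconazole mixture — the in vitro signature of a
    toxicokinetic interaction between the co-formulant and the AS.
    """
    table = HEPARG_EC50_MG_L if table is None else table
    return table[baseline_label] / table[mixture_label]
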