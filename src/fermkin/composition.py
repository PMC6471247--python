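"""Matrix-composition arithmetic: pectin methylation and phenolic classes.

Apple matrices are characterised by their phenolic profile (% w/w of total
phenolics) and the sugar composition of the purified cell walls (mg per g of
alcohol-insoluble solids, AIS).  Two derived quantities matter downstream:
the degree of methylation of the pectin and the summed share of each
phenolic compound class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "CompositionRecord",
    "degree_of_methylation",
    "phenolic_class_shares",
    "PHENOLIC_CLASSES",
    "MM_METHANOL",
    "MM_ANHYDROGALACTURONIC_ACID",
]

#: g/mol of methanol.
MM_METHANOL = 32.04
#: g/mol of the anhydrogalacturonic-acid residue as it occurs in polymeric
#: pectin (the free acid, 194.14 g/mol, is not the in-polymer species).
MM_ANHYDROGALACTURONIC_ACID = 176.13

#: Compound-code -> class grouping for apple phenolics.  CAT/EPI: catechin
#: and epicatechin monomers; PCA: procyanidins; PLX/PLZ: phloretin
#: xyloglucoside and phloridzin; 5CQA/pCQA: caffeoyl- and coumaroylquinic
#: acids; TotalFl: quercetin glycosides; EC/CYA: anthocyanins.
PHENOLIC_CLASSES: dict[str, str] = {
    "CAT": "flavan-3-ols",
    "EPI": "flavan-3-ols",
    "PCA": "flavan-3-ols",
    "PLX": "dihydrochalcones",
    "PLZ": "dihydrochalcones",
    "5CQA": "hydroxycinnamic acids",
    "pCQA": "hydroxycinnamic acids",
    "TotalFl": "flavonols",
    "EC": "anthocyanins",
    "CYA": "anthocyanins",
}


@dataclass
class CompositionRecord:
    """Composition of one matrix.

    ``phenolics`` maps compound codes to % w/w of total phenolic compounds;
    ``cellwall`` maps sugars to mg/g AIS; ``methanol`` is mg/g AIS; ``dpn``
    (mean degree of polymerisation of procyanidins) is carried as data.
    """

    matrix_id: str
    phenolics: dict[str, float] = field(default_factory=dict)
    cellwall: dict[str, float] = field(default_factory=dict)
    methanol: float = 0.0
    dpn: float | None = None

    def __post_init__(self) -> None:
        for name, mapping in (("phenolics", self.phenolics), ("cellwall", self.cellwall)):
            for k, v in mapping.items():
                if v < 0:
                    raise ValueError(f"{name}[{k!r}] must be >= 0")
        if self.methanol < 0:
            raise ValueError("methanol must be >= 0")
        if self.phenolics:
            total = sum(self.phenolics.values())
            if abs(total - 100.0) > 1.0:
                raise ValueError(
                    f"phenolic shares must sum to 100 +/- 1 (rounding), got {total:.2f}"
                )


def degree_of_methylation(methanol: float, galacturonic_acid: float) -> float:
    """Degree of methylation (%) of pectin: the molar ratio of methanol to
    galacturonic acid.

    Both inputs in mg/g AIS.  The galacturonic acid measured in cell walls is
    the polymeric (anhydro) residue, so its molar mass is 176.13 g/mol.
    Returned unrounded; presentation typically rounds to the integer.

    Raises
    ------
    ValueError
        Zero or negative galacturonic acid, or negative methanol.
    """
    if galacturonic_acid <= 0:
        raise ValueError("galacturonic acid must be > 0")
    if methanol < 0:
        raise ValueError("methanol must be >= 0")
    return 100.0 * (methanol / MM_METHANOL) / (
        galacturonic_acid / MM_ANHYDROGALACTURONIC_ACID
    )


def phenolic_class_shares(record: CompositionRecord) -> dict[str, float]:
    """Sum the per-compound shares of a matrix into compound classes.

    Returns a map class -> summed % w/w; classes with no compound present
    are absent.  The sum of the output equals the sum of the input shares.

    Raises
    ------
    KeyError
        A compound code not covered by :data:`PHENOLIC_CLASSES` (DPn is
        structural data, not a share, and is rejected here too).
    """
    if not record.phenolics:
        raise ValueError("record has no phenolic compounds")
    shares: dict[str, float] = {}
    for code, value in record.phenolics.items():
        if code not in PHENOLIC_CLASSES:
            raise KeyError(
                f"unknown phenolic compound code {code!r}; known codes: "
                f"{sorted(PHENOLIC_CLASSES)}"
            )
        cls = PHENOLIC_CLASSES[code]
        shares[cls] = shares.get(cls, 0.0) + value
    return shares
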