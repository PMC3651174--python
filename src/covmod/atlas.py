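"""Built-in Desikan-Killiany cortical parcellation (34 regions x 2 hemispheres).

Node order everywhere in the package is the atlas index order 1..68; odd
indices are left-hemisphere regions, even indices right-hemisphere. Region
abbreviations are suffixed ``.L`` / ``.R`` so that every node label is unique.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

# (full anatomical name, abbreviation), in atlas index order: entry k covers
# indices 2k+1 (left) and 2k+2 (right).
_DK_REGIONS: tuple[tuple[str, str], ...] = (
    ("Bank of the superior temporal sulcus", "BSTS"),
    ("Caudal anterior cingulate", "CAC"),
    ("Caudal middle frontal", "CMF"),
    ("Cuneus", "CUN"),
    ("Entorhinal", "ENT"),
    ("Fusiform gyrus", "FUSI"),
    ("Inferior parietal", "IP"),
    ("Inferior temporal", "IT"),
    ("Isthmus of the cingulate", "ISTC"),
    ("Lateral occipital", "LOCC"),
    ("Lateral orbitofrontal", "LOF"),
    ("Lingual gyrus", "LING"),
    ("Medial orbitofrontal", "MOF"),
    ("Middle temporal", "MT"),
    ("Parahippocampal", "PHG"),
    ("Paracentral lobule", "PARC"),
    ("Pars opercularis (Inferior frontal)", "POPE"),
    ("Pars orbitalis (Inferior frontal)", "PORB"),
    ("Pars triangularis (Inferior frontal)", "PTRI"),
    ("Pericalcarine", "PERI"),
    ("Postcentral gyrus", "PSTC"),
    ("Posterior cingulate", "PC"),
    ("Precentral gyrus", "PREC"),
    ("Precuneus", "PCUN"),
    ("Rostral anterior cingulate", "RAC"),
    ("Rostral middle frontal", "RMF"),
    ("Superior frontal", "SF"),
    ("Superior parietal", "SP"),
    ("Superior temporal", "ST"),
    ("Supramarginal", "SMAR"),
    ("Frontal pole", "FP"),
    ("Temporal pole", "TP"),
    ("Transverse temporal", "TT"),
    ("Insula", "INS"),
)


@dataclass(frozen=True)
class ROIAtlas:
    """A cortical parcellation: ordered ROI labels with names and hemispheres.

    Attributes
    ----------
    table : pandas.DataFrame
        Columns ``index`` (1-based), ``abbreviation`` (hemisphere-suffixed,
        e.g. ``POPE.L``), ``name`` and ``hemisphere`` (``L``/``R``), one row
        per ROI in canonical node order.
    """

    table: pd.DataFrame = field(repr=False)

    @property
    def n_rois(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> list[str]:
        """Hemisphere-suffixed abbreviations in canonical node order."""
        return self.table["abbreviation"].tolist()

    def abbreviation(self, index: int) -> str:
        """Hemisphere-suffixed abbreviation for a 1-based atlas index."""
        row = self.table[self.table["index"] == index]
        if row.empty:
            raise KeyError(f"no ROI with atlas index {index}")
        return row["abbreviation"].iloc[0]

    def index_of(self, abbreviation: str) -> int:
        """1-based atlas index of a hemisphere-suffixed abbreviation."""
        row = self.table[self.table["abbreviation"] == abbreviation]
        if row.empty:
            raise KeyError(f"no ROI with abbreviation {abbreviation!r}")
        return int(row["index"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def builtin_dk_atlas() -> ROIAtlas:
    """The 68-region Desikan-Killiany atlas in canonical node order.

    Odd 1-based indices are left-hemisphere regions, even indices
    right-hemisphere; abbreviations are suffixed ``.L`` / ``.R`` accordingly.
    """
    rows = []
    for k, (name, abbr) in enumerate(_DK_REGIONS):
        rows.append((2 * k + 1, f"{abbr}.L", name, "L"))
        rows.append((2 * k + 2, f"{abbr}.R", name, "R"))
    table = pd.DataFrame(rows, columns=["index", "abbreviation", "name", "hemisphere"])
    return ROIAtlas(table=table)
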