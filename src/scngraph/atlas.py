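"""Region parcellation for the covariance network.

The network nodes are the 90 cortical and subcortical regions of the
Automated Anatomical Labeling (AAL) atlas.  Regions are indexed 1..90 in
the conventional AAL order, odd indices left hemisphere, even indices the
right-hemisphere homolog, so region ``2k-1`` and ``2k`` form a homotopic
pair.  Each region carries a lobe label used for reporting and as the
coarse anatomical grouping of hub tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Atlas", "aal90", "generic_atlas", "read_atlas", "write_atlas"]

# (abbreviation, lobe) for the 45 homotopic pairs, AAL order.
_AAL90_PAIRS: list[tuple[str, str]] = [
    ("PreCG", "frontal"),
    ("SFGdor", "frontal"),
    ("ORBsup", "frontal"),
    ("MFG", "frontal"),
    ("ORBmid", "frontal"),
    ("IFGoperc", "frontal"),
    ("IFGtriang", "frontal"),
    ("ORBinf", "frontal"),
    ("ROL", "frontal"),
    ("SMA", "frontal"),
    ("OLF", "frontal"),
    ("SFGmed", "frontal"),
    ("ORBsupmed", "frontal"),
    ("REC", "frontal"),
    ("INS", "insula"),
    ("ACG", "limbic"),
    ("DCG", "limbic"),
    ("PCG", "limbic"),
    ("HIP", "limbic"),
    ("PHG", "limbic"),
    ("AMYG", "subcortical"),
    ("CAL", "occipital"),
    ("CUN", "occipital"),
    ("LING", "occipital"),
    ("SOG", "occipital"),
    ("MOG", "occipital"),
    ("IOG", "occipital"),
    ("FFG", "temporal"),
    ("PoCG", "parietal"),
    ("SPG", "parietal"),
    ("IPL", "parietal"),
    ("SMG", "parietal"),
    ("ANG", "parietal"),
    ("PCUN", "parietal"),
    ("PCL", "frontal"),
    ("CAU", "subcortical"),
    ("PUT", "subcortical"),
    ("PAL", "subcortical"),
    ("THA", "subcortical"),
    ("HES", "temporal"),
    ("STG", "temporal"),
    ("TPOsup", "temporal"),
    ("MTG", "temporal"),
    ("TPOmid", "temporal"),
    ("ITG", "temporal"),
]

_REQUIRED_COLS = ["region_index", "region_name", "hemisphere", "lobe"]


@dataclass(frozen=True)
class Atlas:
    """A validated region parcellation.

    Parameters
    ----------
    table
        One row per region with columns ``region_index`` (1-based,
        contiguous), ``region_name`` (unique label), ``hemisphere``
        (``left``/``right``) and ``lobe``.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in _REQUIRED_COLS if c not in t.columns]
        if missing:
            raise ValueError(f"atlas table is missing columns: {missing}")
        idx = np.asarray(t["region_index"], dtype=int)
        if len(np.unique(idx)) != len(idx) or not np.array_equal(
            np.sort(idx), np.arange(1, len(idx) + 1)
        ):
            raise ValueError("region_index must be unique and contiguous from 1")
        if t["region_name"].duplicated().any():
            dupes = t.loc[t["region_name"].duplicated(), "region_name"].tolist()
            raise ValueError(f"duplicate region names: {dupes}")
        bad_hemi = set(t["hemisphere"]) - {"left", "right"}
        if bad_hemi:
            raise ValueError(f"unknown hemisphere labels: {sorted(bad_hemi)}")
        if t["lobe"].isna().any() or (t["lobe"] == "").any():
            raise ValueError("every region needs a lobe label")
        # canonical ordering by index
        object.__setattr__(
            self, "table", t.sort_values("region_index").reset_index(drop=True)
        )

    @property
    def n_regions(self) -> int:
        return len(self.table)

    @property
    def names(self) -> list[str]:
        return self.table["region_name"].tolist()

    @property
    def lobes(self) -> pd.Series:
        return self.table.set_index("region_name")["lobe"]

    def homotopic_pairs(self) -> list[tuple[int, int]]:
        """0-based index pairs of left/right homologs.

        Pairs are matched by stripping a trailing ``.L``/``.R`` from the
        region name; regions without a contralateral partner are skipped.
        """
        stem: dict[str, dict[str, int]] = {}
        for i, (name, hemi) in enumerate(
            zip(self.table["region_name"], self.table["hemisphere"])
        ):
            base = name[:-2] if name.endswith((".L", ".R")) else name
            stem.setdefault(base, {})[hemi] = i
        pairs = [
            (d["left"], d["right"]) for d in stem.values() if {"left", "right"} <= d.keys()
        ]
        return sorted(pairs)


def aal90() -> Atlas:
    """The default 90-region AAL parcellation (cortex + subcortex)."""
    rows = []
    for k, (abbr, lobe) in enumerate(_AAL90_PAIRS):
        rows.append((2 * k + 1, f"{abbr}.L", "left", lobe))
        rows.append((2 * k + 2, f"{abbr}.R", "right", lobe))
    return Atlas(pd.DataFrame(rows, columns=_REQUIRED_COLS))


def generic_atlas(n_regions: int) -> Atlas:
    """A synthetic parcellation for arbitrary region counts.

    Regions come in homotopic pairs ``ROIk.L``/``ROIk.R`` with pseudo-lobes
    of six consecutive regions; used for small test problems where the
    anatomical labels of :func:`aal90` are irrelevant.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    rows = []
    for i in range(n_regions):
        pair, hemi = divmod(i, 2)
        name = f"ROI{pair + 1}.{'L' if hemi == 0 else 'R'}"
        if n_regions % 2 == 1 and i == n_regions - 1:
            name, hemi = f"ROI{pair + 1}.L", 0
        rows.append((i + 1, name, "left" if hemi == 0 else "right", f"lobe{i // 6 + 1}"))
    return Atlas(pd.DataFrame(rows, columns=_REQUIRED_COLS))


def write_atlas(atlas: Atlas, path) -> None:
    atlas.table.to_csv(path, index=False)


def read_atlas(path) -> Atlas:
    return Atlas(pd.read_csv(path))
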