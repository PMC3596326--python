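"""Node-distance ages and linear structure clocks.

A rooted tree of fold families induces a relative chronology: the number
of internal nodes between the root (the hypothetical ancestral structure)
and a leaf, rescaled to [0, 1], is the leaf's node distance ``nd`` —
0 for the most basal (oldest) family, 1 for the most derived.  Calibrating
``nd`` against geological markers yields linear "structure clocks" that
convert relative ages to time in Gy before present.  The two published
calibrations shipped here are::

    fold level:  t = -3.802 nd + 3.814
    FSF  level:  t = -3.831 nd + 3.628

with t in Gy.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

from .coding import fsf_of

PROVENANCE_TREE = "tree"
PROVENANCE_SECONDARY = "fallback_secondary_table"
PROVENANCE_FSF_MAX = "fallback_fsf_max"


class AgeTable:
    """Relative ages (node distances) of fold families.

    Maps family ID -> nd in [0, 1] (0 = oldest), with a provenance tag per
    entry recording whether the value came from the tree itself, from a
    secondary age table, or from the oldest FF of the same FSF.
    """

    def __init__(
        self,
        nd: Mapping[str, float],
        provenance: Mapping[str, str] | None = None,
    ):
        self._nd: dict[str, float] = {}
        self._prov: dict[str, str] = {}
        provenance = provenance or {}
        for fam, value in nd.items():
            value = float(value)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"nd for {fam!r} outside [0, 1]: {value}")
            self._nd[str(fam)] = value
            self._prov[str(fam)] = provenance.get(fam, PROVENANCE_TREE)

    def __contains__(self, family: str) -> bool:
        return family in self._nd

    def __len__(self) -> int:
        return len(self._nd)

    def __getitem__(self, family: str) -> float:
        return self._nd[family]

    def get(self, family: str, default=None):
        return self._nd.get(family, default)

    def provenance(self, family: str) -> str:
        return self._prov[family]

    def families(self) -> list[str]:
        return list(self._nd)

    def items(self):
        return self._nd.items()

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": list(self._nd),
                "nd": list(self._nd.values()),
                "provenance": [self._prov[f] for f in self._nd],
            }
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AgeTable)
            and self._nd == other._nd
            and self._prov == other._prov
        )

    def __repr__(self) -> str:
        return f"<AgeTable {len(self)} families>"


def node_distances(tree: dendropy.Tree, normalization: str = "minmax") -> AgeTable:
    """Relative node-distance ages of the leaves of a rooted tree.

    The depth of a leaf is the number of internal nodes on the path from
    the root to the leaf, the root included.  Depths are rescaled to
    [0, 1]: with the default ``"minmax"`` normalization nd =
    (d - d_min) / (d_max - d_min); ``"root"`` uses (d - 1) / (d_max - 1).
    If all leaves are equally deep every nd is 0.
    """
    if tree.seed_node is None or tree.seed_node.is_leaf():
        raise ValueError("node_distances requires a rooted tree with at least one split")
    if normalization not in ("minmax", "root"):
        raise ValueError(f"unknown normalization {normalization!r}")
    depths: dict[str, int] = {}
    for leaf in tree.leaf_node_iter():
        d = 0
        node = leaf.parent_node
        while node is not None:
            d += 1
            node = node.parent_node
        label = leaf.taxon.label if leaf.taxon is not None else leaf.label
        depths[str(label)] = d
    d_arr = np.array(list(depths.values()), dtype=float)
    d_min, d_max = d_arr.min(), d_arr.max()
    lo = d_min if normalization == "minmax" else 1.0
    span = d_max - lo
    nd = {
        fam: (0.0 if span == 0 else (d - lo) / span) for fam, d in depths.items()
    }
    return AgeTable(nd, {fam: PROVENANCE_TREE for fam in nd})


@dataclasses.dataclass(frozen=True)
class MolecularClock:
    """Linear map from node distance to geological time, t = slope*nd + intercept (Gy)."""

    slope: float
    intercept: float
    level: str = "custom"

    def age(self, nd: float) -> float:
        return clock_age(nd, self)


#: Published fold-level structure clock.
FOLD_CLOCK = MolecularClock(slope=-3.802, intercept=3.814, level="fold")
#: Published FSF-level structure clock.
FSF_CLOCK = MolecularClock(slope=-3.831, intercept=3.628, level="FSF")

CLOCKS = {"fold": FOLD_CLOCK, "FSF": FSF_CLOCK, "fsf": FSF_CLOCK}


def clock_age(nd: float, clock: MolecularClock = FOLD_CLOCK) -> float:
    """Geological age in Gy of a structure with relative age ``nd``.

    Negative results (possible for nd near 1 under some calibrations) are
    clamped to 0 with a warning rather than raising, so rounding noise at
    the recent end of the scale cannot crash a pipeline.
    """
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd outside [0, 1]: {nd}")
    t = clock.slope * nd + clock.intercept
    if t < 0:
        warnings.warn(
            f"clock age {t:.4f} Gy at nd={nd} is negative; clamping to 0",
            stacklevel=2,
        )
        t = 0.0
    return t


@dataclasses.dataclass(frozen=True)
class ClockCalibration:
    """OLS fit of geological age against node distance."""

    clock: MolecularClock
    r_value: float
    p_value: float
    stderr: float
    n: int

    def summary(self) -> str:
        c = self.clock
        return (
            f"Structure clock ({c.level}): t = {c.slope:+.4f} nd {c.intercept:+.4f} Gy\n"
            f"  n = {self.n}, Pearson r = {self.r_value:.4f}, "
            f"p = {self.p_value:.3g}, slope SE = {self.stderr:.4f}"
        )


def calibrate_clock(
    pairs: Iterable[tuple[float, float]] | pd.DataFrame, level: str = "custom"
) -> ClockCalibration:
    """Fit a linear structure clock to (nd, age_gy) calibration pairs.

    Ordinary least squares; at least two distinct nd values are required.
    """
    if isinstance(pairs, pd.DataFrame):
        nd = pairs.iloc[:, 0].to_numpy(dtype=float)
        age = pairs.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.array(list(pairs), dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("pairs must be (nd, age_gy) tuples")
        nd, age = arr[:, 0], arr[:, 1]
    if len(np.unique(nd)) < 2:
        raise ValueError("calibration needs at least 2 distinct nd values")
    fit = stats.linregress(nd, age)
    clock = MolecularClock(slope=float(fit.slope), intercept=float(fit.intercept), level=level)
    return ClockCalibration(
        clock=clock,
        r_value=float(fit.rvalue),
        p_value=float(fit.pvalue),
        stderr=float(fit.stderr),
        n=len(nd),
    )


def resolve_age(
    ff: str,
    primary: AgeTable,
    secondary: AgeTable | None = None,
    fsf_groups: Mapping[str, Sequence[str]] | None = None,
) -> tuple[float, str]:
    """Age of a fold family with the documented fallback chain.

    Returns ``(nd, provenance)``: the primary table's value if present;
    otherwise the secondary table's; otherwise the largest nd among FFs of
    the same FSF found in the primary table.  ``fsf_groups`` maps an FF to
    its FSF siblings; when omitted, siblings are derived from the ccs
    (same class.F.FSF prefix) of the primary table's families.
    """
    if ff in primary:
        return primary[ff], PROVENANCE_TREE
    if secondary is not None and ff in secondary:
        return secondary[ff], PROVENANCE_SECONDARY
    if fsf_groups is not None:
        siblings = [s for s in fsf_groups.get(ff, []) if s in primary]
    else:
        try:
            fsf = fsf_of(ff)
        except ValueError:
            siblings = []
        else:
            siblings = [
                fam
                for fam in primary.families()
                if fam != ff and _safe_fsf(fam) == fsf
            ]
    if siblings:
        return max(primary[s] for s in siblings), PROVENANCE_FSF_MAX
    raise KeyError(
        f"fold family {ff!r} unresolvable: absent from primary and secondary "
        "tables and no FSF sibling has an age"
    )


def _safe_fsf(family: str) -> str | None:
    try:
        return fsf_of(family)
    except ValueError:
        return None
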