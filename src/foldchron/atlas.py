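"""Mapping fold-family ages onto enzymatic networks.

An :class:`EnzymeNetwork` is a set of EC-numbered reaction steps, each
carrying one or more pathway labels (e.g. the purine INT / BIO / CAT
pathways) and the SCOP fold families (ccs) of the catalytic domains.
Painting the network with node-distance ages and reading off per-pathway
first appearances, accumulation curves and recruitment classes dates the
origin of each pathway and shows how existing domains were reused as the
network grew.
"""

from __future__ import annotations

import dataclasses
import re
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .chronology import AgeTable, MolecularClock, clock_age

_EC_RE = re.compile(r"^(\d+|-)\.(\d+|-)\.(\d+|-)\.(\d+|-)$")

RECRUIT_INTER = "inter_pathway"
RECRUIT_INTRA = "intra_pathway"
RECRUIT_UNIQUE = "unique"


def ec_matches(pattern: str, ec: str) -> bool:
    """EC comparison with '-' wildcards, e.g. '6.3.4.-' matches '6.3.4.18'."""
    p_parts, e_parts = pattern.split("."), ec.split(".")
    if len(p_parts) != 4 or len(e_parts) != 4:
        return False
    return all(p in ("-", e) or e == "-" for p, e in zip(p_parts, e_parts))


@dataclasses.dataclass(frozen=True)
class Step:
    """One EC-numbered reaction step of an enzymatic network."""

    step_id: str
    ec: str
    pathways: frozenset[str]
    families: frozenset[str]
    substrate: str | None = None
    product: str | None = None

    def __post_init__(self):
        if not _EC_RE.match(self.ec):
            raise ValueError(f"malformed EC number {self.ec!r} in step {self.step_id!r}")
        if not self.pathways:
            raise ValueError(f"step {self.step_id!r} has no pathway label")


class EnzymeNetwork:
    """EC-labeled reaction steps with pathway labels and domain assignments."""

    def __init__(self, steps: Iterable[Step]):
        self.steps: list[Step] = list(steps)
        seen = set()
        for s in self.steps:
            if s.step_id in seen:
                raise ValueError(f"duplicate step_id {s.step_id!r}")
            seen.add(s.step_id)

    @classmethod
    def from_records(cls, records: Iterable[dict]) -> "EnzymeNetwork":
        def split(x):
            if isinstance(x, str):
                return frozenset(t.strip() for t in x.split(",") if t.strip())
            return frozenset(x)

        return cls(
            Step(
                step_id=str(r["step_id"]),
                ec=str(r["ec"]),
                pathways=split(r["pathways"]),
                families=split(r["families"]),
                substrate=r.get("substrate") or None,
                product=r.get("product") or None,
            )
            for r in records
        )

    @classmethod
    def from_tsv(cls, path) -> "EnzymeNetwork":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        required = {"step_id", "ec", "pathways", "families"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"network TSV missing columns: {sorted(missing)}")
        return cls.from_records(df.to_dict("records"))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_id": [s.step_id for s in self.steps],
                "ec": [s.ec for s in self.steps],
                "pathways": [",".join(sorted(s.pathways)) for s in self.steps],
                "families": [",".join(sorted(s.families)) for s in self.steps],
                "substrate": [s.substrate or "" for s in self.steps],
                "product": [s.product or "" for s in self.steps],
            }
        )

    def pathways(self) -> set[str]:
        return set().union(*(s.pathways for s in self.steps)) if self.steps else set()

    def families(self) -> set[str]:
        return set().union(*(s.families for s in self.steps)) if self.steps else set()

    def pathway_steps(self, pathway: str) -> list[Step]:
        return [s for s in self.steps if pathway in s.pathways]

    def pathway_families(self, pathway: str) -> set[str]:
        fams: set[str] = set()
        for s in self.pathway_steps(pathway):
            fams |= s.families
        return fams

    def steps_with_family(self, ff: str) -> list[Step]:
        return [s for s in self.steps if ff in s.families]

    def steps_matching_ec(self, pattern: str) -> list[Step]:
        return [s for s in self.steps if ec_matches(pattern, s.ec)]

    def __len__(self) -> int:
        return len(self.steps)

    def __repr__(self) -> str:
        return (
            f"<EnzymeNetwork {len(self.steps)} steps, "
            f"{len(self.families())} families, pathways {sorted(self.pathways())}>"
        )


def _require_ages(families: Iterable[str], ages: AgeTable) -> None:
    missing = sorted(f for f in families if f not in ages)
    if missing:
        raise KeyError(
            f"no resolved age for fold families {missing}; resolve ages "
            "(resolve_age fallbacks) before pathway mapping"
        )


def pathway_first_appearance(net: EnzymeNetwork, ages: AgeTable, pathway: str) -> float:
    """Node distance at which a pathway first appears: the minimum nd over
    all fold families assigned to any of its steps."""
    fams = net.pathway_families(pathway)
    if not fams:
        raise ValueError(f"pathway {pathway!r} has no steps with domain assignments")
    _require_ages(fams, ages)
    return min(ages[f] for f in fams)


def pathway_completion(net: EnzymeNetwork, ages: AgeTable, pathway: str) -> float:
    """Node distance at which the pathway's full FF repertoire is in place
    (maximum nd over its fold families)."""
    fams = net.pathway_families(pathway)
    if not fams:
        raise ValueError(f"pathway {pathway!r} has no steps with domain assignments")
    _require_ages(fams, ages)
    return max(ages[f] for f in fams)


def accumulation_curve(
    net: EnzymeNetwork, ages: AgeTable, pathway: str
) -> list[tuple[float, int]]:
    """Step function of distinct fold-family counts along the timeline.

    Returns ordered (nd, cumulative count) pairs: the number of distinct
    FFs of the pathway with age <= nd, one pair per distinct appearance
    time.  Empty pathways give an empty curve.
    """
    fams = net.pathway_families(pathway)
    if not fams:
        return []
    _require_ages(fams, ages)
    nd_values = sorted(ages[f] for f in fams)
    curve: list[tuple[float, int]] = []
    for i, nd in enumerate(nd_values, start=1):
        if curve and curve[-1][0] == nd:
            curve[-1] = (nd, i)
        else:
            curve.append((nd, i))
    return curve


@dataclasses.dataclass(frozen=True)
class RecruitmentEvent:
    """How one fold family is deployed across the network's steps."""

    ff: str
    nd: float
    pathways_sharing: frozenset[str]
    steps_sharing: frozenset[str]
    recruitment_class: str


def classify_recruitment(net: EnzymeNetwork, ages: AgeTable) -> list[RecruitmentEvent]:
    """One event per fold family, sorted by age (oldest first).

    inter_pathway: its steps span >= 2 pathway labels; intra_pathway: one
    pathway but >= 2 steps; unique: exactly one step.
    """
    events = []
    fams = net.families()
    _require_ages(fams, ages)
    for ff in sorted(fams):
        steps = net.steps_with_family(ff)
        pathways = frozenset().union(*(s.pathways for s in steps))
        if len(pathways) >= 2:
            cls = RECRUIT_INTER
        elif len(steps) >= 2:
            cls = RECRUIT_INTRA
        else:
            cls = RECRUIT_UNIQUE
        events.append(
            RecruitmentEvent(
                ff=ff,
                nd=ages[ff],
                pathways_sharing=pathways,
                steps_sharing=frozenset(s.ec for s in steps),
                recruitment_class=cls,
            )
        )
    events.sort(key=lambda e: (e.nd, e.ff))
    return events


@dataclasses.dataclass(frozen=True)
class PathwayTimeline:
    """First appearance and completion of one pathway, in nd and Gy."""

    pathway: str
    first_nd: float
    completion_nd: float
    first_age_gy: float
    completion_age_gy: float
    accumulation: tuple[tuple[float, int], ...]


def build_timeline(
    net: EnzymeNetwork,
    ages: AgeTable,
    clock: MolecularClock,
    pathways: Sequence[str] | None = None,
    landmarks: Sequence[tuple[float, str]] | None = None,
) -> dict[str, PathwayTimeline]:
    """Per-pathway origin/completion table on both the nd and Gy scales.

    ``landmarks`` are free (nd, label) annotation pairs accepted for
    rendering; they do not affect the computed timelines.
    """
    del landmarks  # annotations only; carried by plotting/export layers
    selected = list(pathways) if pathways is not None else sorted(net.pathways())
    out: dict[str, PathwayTimeline] = {}
    for pw in selected:
        first = pathway_first_appearance(net, ages, pw)
        comp = pathway_completion(net, ages, pw)
        out[pw] = PathwayTimeline(
            pathway=pw,
            first_nd=first,
            completion_nd=comp,
            first_age_gy=clock_age(first, clock),
            completion_age_gy=clock_age(comp, clock),
            accumulation=tuple(accumulation_curve(net, ages, pw)),
        )
    return out


def timeline_dataframe(timelines: dict[str, PathwayTimeline]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway": list(timelines),
            "first_nd": [t.first_nd for t in timelines.values()],
            "completion_nd": [t.completion_nd for t in timelines.values()],
            "first_age_gy": [t.first_age_gy for t in timelines.values()],
            "completion_age_gy": [t.completion_age_gy for t in timelines.values()],
        }
    )


def age_color(nd: float) -> str:
    """Hex color on the continuous red (nd=0, oldest) -> blue (nd=1) ramp."""
    if not 0.0 <= nd <= 1.0:
        raise ValueError(f"nd outside [0, 1]: {nd}")
    r = round(255 * (1.0 - nd))
    b = round(255 * nd)
    return f"#{r:02x}00{b:02x}"


def paint_network(net: EnzymeNetwork, ages: AgeTable) -> nx.Graph:
    """Age-painted network graph.

    Each step becomes a node colored by the minimum nd among its fold
    families (an enzyme exists once any of its catalytic domains does);
    all per-FF ages are kept as a node annotation.  Steps sharing a
    metabolite (one's product is another's substrate) are connected.
    The graph serializes with ``networkx`` GraphML writers or via
    :func:`to_dot`.
    """
    _require_ages(net.families(), ages)
    g = nx.Graph()
    for s in net.steps:
        fam_ages = {f: ages[f] for f in sorted(s.families)}
        nd = min(fam_ages.values())
        g.add_node(
            s.step_id,
            ec=s.ec,
            pathways=",".join(sorted(s.pathways)),
            families=",".join(f"{f}={a:g}" for f, a in fam_ages.items()),
            nd=nd,
            color=age_color(nd),
        )
    for a in net.steps:
        for b in net.steps:
            if a.step_id < b.step_id and a.product and a.product == b.substrate:
                g.add_edge(a.step_id, b.step_id, metabolite=a.product)
            elif a.step_id < b.step_id and b.product and b.product == a.substrate:
                g.add_edge(a.step_id, b.step_id, metabolite=b.product)
    return g


def to_dot(g: nx.Graph) -> str:
    """Render a painted network as a Graphviz DOT document."""
    lines = ["graph enzyme_network {", "  node [style=filled, fontcolor=white];"]
    for node, attrs in g.nodes(data=True):
        label = f"{attrs.get('ec', '')}\\n{node}\\nnd={attrs.get('nd', float('nan')):g}"
        lines.append(
            f'  "{node}" [label="{label}", fillcolor="{attrs.get("color", "#888888")}"];'
        )
    for u, v, attrs in g.edges(data=True):
        met = attrs.get("metabolite")
        suffix = f' [label="{met}"]' if met else ""
        lines.append(f'  "{u}" -- "{v}"{suffix};')
    lines.append("}")
    return "\n".join(lines) + "\n"
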