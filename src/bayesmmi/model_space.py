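"""Combinatorial enumeration of candidate cell-population models.

A candidate model is one mechanistic hypothesis about a heterogeneous tumor:
which cell subtypes are present (the topology), which subtype(s) seed the
tumor, which phenotypic transitions connect subtypes, and whether Non-NE
subtypes modulate the division, death or transition rates of the others.
The hypothesis space is built combinatorially from biologically motivated
axes and then deduplicated, so that each surviving candidate is a distinct
mechanistic explanation that can be fit to subtype-proportion data.

Subtypes are the four canonical neuroendocrine (NE) / non-neuroendocrine
(Non-NE) tumor cell states A, N, A2 and Y.  A and N are NE, Y is Non-NE,
and A2 carries markers of both classes, so its class is a per-candidate
assignment.  The developmental hierarchy runs A -> (N, A2) -> Y.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

__all__ = [
    "Subtype",
    "Topology",
    "RuleSpec",
    "RuleCatalog",
    "InitiationScheme",
    "CandidateModel",
    "EnumerationConfig",
    "SUBTYPE_ORDER",
    "HIERARCHICAL_TRANSITIONS",
    "NON_HIERARCHICAL_TRANSITIONS",
    "LATE_TRANSITIONS",
    "EARLY_TRANSITIONS",
    "enumerate_topologies",
    "build_rule_catalog",
    "initiation_schemes",
    "enumerate_candidates",
    "candidate_filter",
    "paper_config",
    "naive_space_size",
    "candidates_to_frame",
    "write_candidates_csv",
    "write_model_definition",
    "read_model_definition",
]

#: Canonical subtype ordering used everywhere (display, hashing, CSV).
SUBTYPE_ORDER: tuple[str, ...] = ("A", "N", "A2", "Y")

#: Transitions that follow the developmental hierarchy A -> (N, A2) -> Y.
HIERARCHICAL_TRANSITIONS: tuple[tuple[str, str], ...] = (
    ("A", "N"),
    ("A", "A2"),
    ("N", "Y"),
    ("A2", "Y"),
)

#: The remaining 8 directed pairs; these never carry inter-subtype effects.
NON_HIERARCHICAL_TRANSITIONS: tuple[tuple[str, str], ...] = tuple(
    (a, b)
    for a in SUBTYPE_ORDER
    for b in SUBTYPE_ORDER
    if a != b and (a, b) not in HIERARCHICAL_TRANSITIONS
)

#: Hierarchy steps into the terminal Non-NE state Y ("late" steps).
LATE_TRANSITIONS: frozenset[tuple[str, str]] = frozenset({("N", "Y"), ("A2", "Y")})
#: Hierarchy steps out of the root state A ("early" steps).
EARLY_TRANSITIONS: frozenset[tuple[str, str]] = frozenset({("A", "N"), ("A", "A2")})

_ORDER_INDEX = {s: i for i, s in enumerate(SUBTYPE_ORDER)}


def _sorted_subtypes(names: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(names, key=_ORDER_INDEX.__getitem__))


@dataclass(frozen=True)
class Subtype:
    """A tumor cell state and its NE / Non-NE class.

    A and N are always NE and Y always Non-NE; A2 expresses markers of both
    classes and its ``ne_class`` is therefore a per-candidate assignment.
    """

    name: str
    ne_class: str  # "NE" or "NonNE"

    def __post_init__(self) -> None:
        if self.name not in SUBTYPE_ORDER:
            raise ValueError(f"unknown subtype {self.name!r}")
        if self.ne_class not in ("NE", "NonNE"):
            raise ValueError(f"ne_class must be NE or NonNE, got {self.ne_class!r}")
        fixed = {"A": "NE", "N": "NE", "Y": "NonNE"}
        if self.name in fixed and self.ne_class != fixed[self.name]:
            raise ValueError(f"{self.name} is always {fixed[self.name]}")


@dataclass(frozen=True)
class Topology:
    """The ordered set of subtypes present in a candidate model."""

    subtypes: tuple[str, ...]

    def __post_init__(self) -> None:
        ordered = _sorted_subtypes(self.subtypes)
        if len(set(ordered)) != len(self.subtypes):
            raise ValueError("duplicate subtypes in topology")
        # heterogeneous topologies have 2-4 subtypes; size 1 is admitted only
        # for the homogeneous-tumor baseline model
        if not 1 <= len(ordered) <= 4:
            raise ValueError("topology must contain 1-4 subtypes")
        object.__setattr__(self, "subtypes", ordered)

    def __contains__(self, name: str) -> bool:
        return name in self.subtypes

    def __len__(self) -> int:
        return len(self.subtypes)

    @property
    def label(self) -> str:
        return "+".join(self.subtypes)


@dataclass(frozen=True)
class RuleSpec:
    """One reaction: a division, death or phenotypic transition.

    ``effect_scheme`` records which Non-NE effector population (if any)
    modulates the reaction rate; the modulated rate is
    ``rate * (1 + (m - 1) * w / (K + w))`` with multiplier ``m``, effector
    cell count ``w`` and saturation constant ``K`` (see ``popdyn``).
    """

    kind: str  # "division" | "death" | "transition"
    subject: str
    target: str | None = None
    hierarchy: str = "not_applicable"  # transitions: hierarchical|non_hierarchical
    effect_scheme: str = "none"  # "none" | "Y_only" | "A2_and_Y"

    def __post_init__(self) -> None:
        if self.kind not in ("division", "death", "transition"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if self.kind == "transition":
            if self.target is None or self.target == self.subject:
                raise ValueError("transition needs a distinct target")
            if self.hierarchy not in ("hierarchical", "non_hierarchical"):
                raise ValueError("transition hierarchy must be set")
            if self.hierarchy == "non_hierarchical" and self.effect_scheme != "none":
                raise ValueError("non-hierarchical transitions carry no effects")
        else:
            if self.target is not None:
                raise ValueError(f"{self.kind} rules have no target")
            if self.hierarchy != "not_applicable":
                raise ValueError(f"{self.kind} rules have no hierarchy")
        if self.effect_scheme not in ("none", "Y_only", "A2_and_Y"):
            raise ValueError(f"unknown effect scheme {self.effect_scheme!r}")

    @property
    def effectors(self) -> tuple[str, ...]:
        if self.effect_scheme == "Y_only":
            return ("Y",)
        if self.effect_scheme == "A2_and_Y":
            return ("A2", "Y")
        return ()

    @property
    def rate_param(self) -> str:
        if self.kind == "transition":
            return f"k_tr_{self.subject}_{self.target}"
        stem = "div" if self.kind == "division" else "die"
        return f"k_{stem}_{self.subject}"

    @property
    def effect_param(self) -> str | None:
        if self.effect_scheme == "none":
            return None
        return f"m_{self.rate_param[2:]}"

    @property
    def saturation_param(self) -> str | None:
        if self.effect_scheme == "none":
            return None
        return f"K_{self.rate_param[2:]}"

    @property
    def rule_id(self) -> str:
        base = self.rate_param[2:]
        suffix = {"none": "", "Y_only": "*Y", "A2_and_Y": "*A2Y"}[self.effect_scheme]
        return base + suffix

    def sort_key(self) -> tuple:
        kind_rank = {"division": 0, "death": 1, "transition": 2}[self.kind]
        return (
            kind_rank,
            _ORDER_INDEX[self.subject],
            _ORDER_INDEX.get(self.target, -1) if self.target else -1,
            self.effect_scheme,
        )


@dataclass(frozen=True)
class RuleCatalog:
    """The full reaction catalog over the 4-subtype universe (44 variants)."""

    rules: tuple[RuleSpec, ...]

    def restricted_to(self, topology: Topology) -> tuple[RuleSpec, ...]:
        # an effect rule survives when at least one scheme member is present;
        # the effective effector population is the intersection with the
        # topology (A2_and_Y acts through A2 alone in a Y-less topology)
        keep = []
        for r in self.rules:
            if r.subject not in topology:
                continue
            if r.target is not None and r.target not in topology:
                continue
            if r.effectors and not any(e in topology.subtypes for e in r.effectors):
                continue
            keep.append(r)
        return tuple(keep)

    def __len__(self) -> int:
        return len(self.rules)


def build_rule_catalog(universe: Sequence[str] = SUBTYPE_ORDER) -> RuleCatalog:
    """Build the 44-variant reaction catalog over {A, N, A2, Y}.

    8 division/death reactions x 3 effect options (none, Y, A2+Y) = 24,
    4 hierarchical transitions x 3 effect options = 12, and the 8
    non-hierarchical transitions (no effects) = 8; 44 in total.
    """
    if _sorted_subtypes(universe) != SUBTYPE_ORDER:
        raise ValueError("the reaction catalog is defined over {A, N, A2, Y}")
    rules: list[RuleSpec] = []
    for s in SUBTYPE_ORDER:
        for kind in ("division", "death"):
            for scheme in ("none", "Y_only", "A2_and_Y"):
                rules.append(RuleSpec(kind=kind, subject=s, effect_scheme=scheme))
    for a, b in HIERARCHICAL_TRANSITIONS:
        for scheme in ("none", "Y_only", "A2_and_Y"):
            rules.append(
                RuleSpec(
                    kind="transition",
                    subject=a,
                    target=b,
                    hierarchy="hierarchical",
                    effect_scheme=scheme,
                )
            )
    for a, b in NON_HIERARCHICAL_TRANSITIONS:
        rules.append(
            RuleSpec(kind="transition", subject=a, target=b, hierarchy="non_hierarchical")
        )
    rules.sort(key=RuleSpec.sort_key)
    return RuleCatalog(rules=tuple(rules))


@dataclass(frozen=True)
class InitiationScheme:
    """Which subtypes seed the tumor; 100 cells split equally among them."""

    initiators: tuple[str, ...]
    total_initial_cells: float = 100.0

    def __post_init__(self) -> None:
        if not self.initiators:
            raise ValueError("at least one initiating subtype is required")
        object.__setattr__(self, "initiators", _sorted_subtypes(self.initiators))

    def initial_counts(self, topology: Topology) -> dict[str, float]:
        per = self.total_initial_cells / len(self.initiators)
        return {s: (per if s in self.initiators else 0.0) for s in topology.subtypes}


def enumerate_topologies(universe: Sequence[str]) -> list[Topology]:
    """All subsets of the universe with at least two subtypes, in canonical order."""
    subs = _sorted_subtypes(universe)
    if len(subs) < 2:
        raise ValueError("universe must contain at least 2 subtypes")
    out = []
    for r in range(2, len(subs) + 1):
        for combo in itertools.combinations(subs, r):
            out.append(Topology(subtypes=combo))
    out.sort(key=lambda t: (len(t), tuple(_ORDER_INDEX[s] for s in t.subtypes)))
    return out


def initiation_schemes(topology: Topology) -> list[InitiationScheme]:
    """All 2^n - 1 nonempty initiator subsets of an n-subtype topology."""
    out = []
    subs = topology.subtypes
    for r in range(1, len(subs) + 1):
        for combo in itertools.combinations(subs, r):
            out.append(InitiationScheme(initiators=combo))
    return out


@dataclass(frozen=True)
class CandidateModel:
    """One mechanistic hypothesis: topology + rules + initiation."""

    topology: Topology
    a2_class: str  # "NE" | "NonNE" | "not_present"
    rules: tuple[RuleSpec, ...]
    initiation: InitiationScheme
    identity_key: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.a2_class not in ("NE", "NonNE", "not_present"):
            raise ValueError(f"bad a2_class {self.a2_class!r}")
        ordered = tuple(sorted(self.rules, key=RuleSpec.sort_key))
        object.__setattr__(self, "rules", ordered)
        if not self.identity_key:
            object.__setattr__(self, "identity_key", self._hash_key())

    def _hash_key(self) -> str:
        # identity is rules + initiation only: two candidates differing just
        # in the A2 class label describe the same observable dynamics
        payload = ";".join(r.rule_id for r in self.rules)
        payload += "|init:" + ",".join(self.initiation.initiators)
        return hashlib.sha1(payload.encode()).hexdigest()[:16]

    @property
    def transitions(self) -> tuple[tuple[str, str], ...]:
        return tuple(
            (r.subject, r.target) for r in self.rules if r.kind == "transition"
        )

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for r in self.rules:
            names.append(r.rate_param)
            if r.effect_param:
                names.append(r.effect_param)
                names.append(r.saturation_param)
        # preserve rule order, drop duplicates
        return tuple(dict.fromkeys(names))

    def is_accessible(self) -> bool:
        """Every subtype is an initiator or reachable from one via transitions."""
        seen = set(self.initiation.initiators)
        frontier = list(seen)
        edges = self.transitions
        while frontier:
            x = frontier.pop()
            for a, b in edges:
                if a == x and b not in seen:
                    seen.add(b)
                    frontier.append(b)
        return seen >= set(self.topology.subtypes)


@dataclass(frozen=True)
class EnumerationConfig:
    """The axes of the combinatorial hypothesis space.

    transition_schemes
        Which transition structures are generated per topology:
        "none" (no transitions), "hierarchy" (the full unidirectional
        hierarchy restricted to the topology) and "bidirectional"
        (symmetric two-way transitions over subsets of subtype pairs).
    bidirectional_connected_only
        Restrict bidirectional pair subsets to those forming a connected
        (undirected) graph on the subtypes they touch; plasticity shared
        among subtypes rather than split into isolated islands.
    effect_options
        Global effector choices; "Y_only" requires Y in the topology,
        "A2_and_Y" requires A2 (the effectors are the scheme members that
        are present).
    affected_combos
        Which behaviors an effector modulates.  Each entry pairs a flag
        "does the effect act on growth (division+death of non-effector
        subtypes)" with the set of hierarchical transitions it accelerates:
        "late" (into Y), "early" (out of A), "all" or "none".
    require_accessibility
        Drop initiation schemes leaving a subtype unreachable.
    """

    universe: tuple[str, ...] = SUBTYPE_ORDER
    transition_schemes: tuple[str, ...] = ("none", "hierarchy", "bidirectional")
    bidirectional_connected_only: bool = True
    effect_options: tuple[str, ...] = ("none", "Y_only", "A2_and_Y")
    affected_combos: tuple[tuple[bool, str], ...] = (
        (True, "late"),
        (True, "early"),
        (False, "all"),
    )
    effects_spare_effectors: bool = True
    require_accessibility: bool = True
    include_single_subtype_null: bool = False


def paper_config() -> EnumerationConfig:
    """The calibrated preset reproducing the published hypothesis-space size."""
    return EnumerationConfig(include_single_subtype_null=True)


def naive_space_size(config: EnumerationConfig | None = None) -> float:
    """Size of the unconstrained space: 15 initiations x 2^44 rule subsets."""
    return (2 ** len(SUBTYPE_ORDER) - 1) * 2.0 ** len(build_rule_catalog().rules)


def _transition_edge_sets(
    topology: Topology, config: EnumerationConfig
) -> list[frozenset[tuple[str, str]]]:
    subs = topology.subtypes
    out: set[frozenset] = set()
    if "none" in config.transition_schemes:
        out.add(frozenset())
    if "hierarchy" in config.transition_schemes:
        out.add(
            frozenset(
                (a, b) for a, b in HIERARCHICAL_TRANSITIONS if a in subs and b in subs
            )
        )
    if "bidirectional" in config.transition_schemes:
        pairs = [frozenset(p) for p in itertools.combinations(subs, 2)]
        for r in range(len(pairs) + 1):
            for chosen in itertools.combinations(pairs, r):
                if chosen and config.bidirectional_connected_only:
                    verts = set().union(*chosen)
                    comp = {next(iter(verts))}
                    grew = True
                    while grew:
                        grew = False
                        for p in chosen:
                            if p & comp and not p <= comp:
                                comp |= p
                                grew = True
                    if comp != verts:
                        continue
                edges = set()
                for p in chosen:
                    a, b = _sorted_subtypes(p)
                    edges.add((a, b))
                    edges.add((b, a))
                out.add(frozenset(edges))
    return sorted(out, key=lambda es: (len(es), sorted(es)))


def _effector_sets(topology: Topology, config: EnumerationConfig) -> list[tuple[str, ...]]:
    out: list[tuple[str, ...]] = []
    if "none" in config.effect_options:
        out.append(())
    if "Y_only" in config.effect_options and "Y" in topology:
        out.append(("Y",))
    if "A2_and_Y" in config.effect_options and "A2" in topology:
        out.append(_sorted_subtypes({"A2", "Y"} & set(topology.subtypes)))
    return out


def _scheme_for(effectors: tuple[str, ...]) -> str:
    return "A2_and_Y" if "A2" in effectors else "Y_only"


def enumerate_candidates(config: EnumerationConfig | None = None) -> list[CandidateModel]:
    """Enumerate the deduplicated, biologically constrained candidate set.

    Deterministic: repeated runs return the same ordered list.
    """
    if config is None:
        config = paper_config()
    for opt in config.effect_options:
        if opt != "none" and not (set(opt.split("_and_")) - {"only"}):
            raise ValueError(f"bad effect option {opt!r}")

    seen: dict[str, CandidateModel] = {}
    hier_set = set(HIERARCHICAL_TRANSITIONS)
    affected_map = {
        "late": LATE_TRANSITIONS,
        "early": EARLY_TRANSITIONS,
        "all": hier_set,
        "none": frozenset(),
    }

    if config.include_single_subtype_null:
        # the homogeneous-tumor baseline: a single A compartment that
        # divides, dies, and seeds the tumor alone
        null = CandidateModel(
            topology=Topology(subtypes=("A",)),
            a2_class="not_present",
            rules=(
                RuleSpec(kind="division", subject="A"),
                RuleSpec(kind="death", subject="A"),
            ),
            initiation=InitiationScheme(initiators=("A",)),
        )
        seen[null.identity_key] = null

    for topology in enumerate_topologies(config.universe):
        subs = topology.subtypes
        for edges in _transition_edge_sets(topology, config):
            hed = {e for e in edges if e in hier_set}
            for effectors in _effector_sets(topology, config):
                combos: list[tuple[bool, str] | None]
                combos = [None] if not effectors else list(config.affected_combos)
                for combo in combos:
                    if effectors:
                        grow, tmode = combo
                        affected_tr = hed & affected_map[tmode]
                        if config.effects_spare_effectors:
                            grow_targets = set(subs) - set(effectors)
                        else:
                            grow_targets = set(subs)
                    else:
                        grow, affected_tr, grow_targets = False, set(), set()
                    scheme = _scheme_for(effectors) if effectors else "none"
                    rules: list[RuleSpec] = []
                    for s in subs:
                        eff = scheme if (grow and s in grow_targets) else "none"
                        rules.append(RuleSpec(kind="division", subject=s, effect_scheme=eff))
                        rules.append(RuleSpec(kind="death", subject=s, effect_scheme=eff))
                    for a, b in sorted(edges):
                        if (a, b) in hier_set:
                            eff = scheme if (a, b) in affected_tr else "none"
                            rules.append(
                                RuleSpec(
                                    kind="transition",
                                    subject=a,
                                    target=b,
                                    hierarchy="hierarchical",
                                    effect_scheme=eff,
                                )
                            )
                        else:
                            rules.append(
                                RuleSpec(
                                    kind="transition",
                                    subject=a,
                                    target=b,
                                    hierarchy="non_hierarchical",
                                )
                            )
                    if "A2" in subs:
                        a2_class = "NonNE" if "A2" in effectors else "NE"
                    else:
                        a2_class = "not_present"
                    for scheme_init in initiation_schemes(topology):
                        cand = CandidateModel(
                            topology=topology,
                            a2_class=a2_class,
                            rules=tuple(rules),
                            initiation=scheme_init,
                        )
                        if config.require_accessibility and not cand.is_accessible():
                            continue
                        seen.setdefault(cand.identity_key, cand)

    out = list(seen.values())
    out.sort(
        key=lambda c: (
            len(c.topology.subtypes),
            tuple(_ORDER_INDEX[s] for s in c.topology.subtypes),
            len(c.rules),
            tuple(r.rule_id for r in c.rules),
            c.initiation.initiators,
        )
    )
    return out


def candidate_filter(
    candidates: Sequence[CandidateModel],
    predicate: Callable[[CandidateModel], bool],
) -> list[CandidateModel]:
    """Order-preserving subset of candidates satisfying a pure predicate."""
    return [c for c in candidates if predicate(c)]


def candidates_to_frame(candidates: Sequence[CandidateModel]):
    """Tabulate candidates (one row each) for export."""
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append(
            {
                "identity_key": c.identity_key,
                "topology": c.topology.label,
                "a2_class": c.a2_class,
                "initiators": "+".join(c.initiation.initiators),
                "n_rules": len(c.rules),
                "rules": ";".join(r.rule_id for r in c.rules),
            }
        )
    return pd.DataFrame(rows)


def write_candidates_csv(candidates: Sequence[CandidateModel], path) -> None:
    candidates_to_frame(candidates).to_csv(path, index=False)


def write_model_definition(config: EnumerationConfig, path) -> None:
    """Write an enumeration run definition as a sectioned CSV.

    Three sections: components (subtype, ne_class), reactions (the rule
    catalog restricted to the universe), and instructions (the
    enumeration axes).  One file defines one enumeration run.
    """
    lines = ["#components", "subtype,ne_class"]
    fixed = {"A": "NE", "N": "NE", "Y": "NonNE", "A2": "NE_or_NonNE"}
    for s in config.universe:
        lines.append(f"{s},{fixed[s]}")
    lines += ["#reactions", "rule_id,kind,subject,target,effect_scheme"]
    for r in build_rule_catalog().rules:
        if r.subject not in config.universe:
            continue
        if r.target is not None and r.target not in config.universe:
            continue
        lines.append(
            f"{r.rule_id},{r.kind},{r.subject},{r.target or ''},{r.effect_scheme}"
        )
    lines += ["#instructions", "key,value"]
    lines.append("universe," + "+".join(config.universe))
    lines.append("transition_schemes," + "+".join(config.transition_schemes))
    lines.append(
        f"bidirectional_connected_only,{config.bidirectional_connected_only}"
    )
    lines.append("effect_options," + "+".join(config.effect_options))
    lines.append(
        "affected_combos,"
        + "+".join(f"{'growth' if g else 'nogrowth'}:{t}" for g, t in config.affected_combos)
    )
    lines.append(f"require_accessibility,{config.require_accessibility}")
    lines.append(f"include_single_subtype_null,{config.include_single_subtype_null}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_model_definition(path) -> EnumerationConfig:
    """Parse the instructions section of a model-definition CSV."""
    instructions: dict[str, str] = {}
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                section = line[1:]
                continue
            if section == "instructions" and line != "key,value":
                if "," not in line:
                    raise ValueError(f"{path}:{lineno}: malformed instruction {line!r}")
                key, value = line.split(",", 1)
                instructions[key] = value
    def flag(key, default):
        return instructions.get(key, str(default)) == "True"
    combos = []
    for item in instructions.get("affected_combos", "").split("+"):
        if not item:
            continue
        g, t = item.split(":")
        combos.append((g == "growth", t))
    base = EnumerationConfig()
    return EnumerationConfig(
        universe=tuple(instructions.get("universe", "+".join(base.universe)).split("+")),
        transition_schemes=tuple(
            instructions.get("transition_schemes", "+".join(base.transition_schemes)).split("+")
        ),
        bidirectional_connected_only=flag(
            "bidirectional_connected_only", base.bidirectional_connected_only
        ),
        effect_options=tuple(
            instructions.get("effect_options", "+".join(base.effect_options)).split("+")
        ),
        affected_combos=tuple(combos) if combos else base.affected_combos,
        require_accessibility=flag("require_accessibility", base.require_accessibility),
        include_single_subtype_null=flag(
            "include_single_subtype_null", base.include_single_subtype_null
        ),
    )
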