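"""The two-high-threshold (2-HT) eyewitness identification model.

Each experimental group contributes two trees. In a culprit-present lineup
the witness may detect the culprit's presence (dP), select the suspect
through lineup bias (b), or guess (g) and then sample the suspect with
probability 1/n (n the lineup size):

    P(culprit id)  = dP + (1-dP) b + (1-dP)(1-b) g (1/n)
    P(filler id)   = (1-dP)(1-b) g (1 - 1/n)
    P(rejection)   = (1-dP)(1-b)(1-g)

In a culprit-absent lineup the witness may detect the culprit's absence
(dA), otherwise bias and guessing operate on the innocent suspect:

    P(suspect id)  = (1-dA) b + (1-dA)(1-b) g (1/n)
    P(filler id)   = (1-dA)(1-b) g (1 - 1/n)
    P(rejection)   = dA + (1-dA)(1-b)(1-g)

The joint multi-group model instantiates these trees once per group with
group-specific parameters dP_k, g_k, b_k, dA_k; the base model equates b
and dA across groups. Hypothesis tests add one further equality (df = 1)
and compare fits via the difference in G2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

from scipy.stats import chi2

from .mpt import (
    Branch,
    Factor,
    FitOptions,
    FitResult,
    FrequencyTable,
    MptError,
    MptModel,
    Parameter,
    RestrictionSet,
    Tree,
    fit,
)

CATEGORIES = ("suspect_id", "filler_id", "rejection")
PRESENT = "present"
ABSENT = "absent"

LOW = "low"
NEUTRAL = "neutral"

#: 5-decimal truncations of 1/n used for reproducing published analyses.
TRUNCATED_SAMPLING = {3: 0.33333, 6: 0.16667}


@dataclass(frozen=True)
class GroupSpec:
    """One experimental group: lineup size and instruction condition.

    ``sampling_constant`` is the probability of sampling the suspect when
    guessing (1/n). By default the published 5-decimal truncations are used
    for n = 3 and n = 6; pass ``exact=True`` for the exact rational 1/n.
    """

    label: str
    lineup_size: int
    instruction: str
    sampling_constant: float | None = None
    exact: bool = False

    def __post_init__(self) -> None:
        if self.lineup_size < 2:
            raise ValueError("lineup size must be at least 2 (no showups)")
        if self.instruction not in (LOW, NEUTRAL):
            raise ValueError(f"unknown instruction condition {self.instruction!r}")

    @property
    def constant(self) -> float:
        if self.sampling_constant is not None:
            if not 0.0 < self.sampling_constant < 1.0:
                raise ValueError("sampling constant must lie in (0, 1)")
            return self.sampling_constant
        if not self.exact and self.lineup_size in TRUNCATED_SAMPLING:
            return TRUNCATED_SAMPLING[self.lineup_size]
        return float(Fraction(1, self.lineup_size))


def study_groups() -> list[GroupSpec]:
    """The four groups of the published 2x2 design (size x instructions)."""
    return [
        GroupSpec("three_low", 3, LOW),
        GroupSpec("three_neutral", 3, NEUTRAL),
        GroupSpec("six_low", 6, LOW),
        GroupSpec("six_neutral", 6, NEUTRAL),
    ]


def tree_name(group: str, lineup_type: str) -> str:
    return f"{group}.{lineup_type}"


def param_name(base: str, group: str) -> str:
    return f"{base}_{group}"


def build_joint_model(groups: Sequence[GroupSpec]) -> MptModel:
    """One culprit-present and one culprit-absent tree per group, with
    group-specific dP, g, b, dA and the group's sampling constant wired in.
    """
    if not groups:
        raise MptError("at least one group is required")
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise MptError("duplicate group labels")

    params: list[Parameter] = []
    trees: list[Tree] = []
    const_names: dict[float, str] = {}
    for g in groups:
        c = g.constant
        if c not in const_names:
            cname = f"c_{len(const_names) + 1}" if g.exact else f"c{g.lineup_size}"
            # name constants by lineup size when unambiguous
            if cname in {v for v in const_names.values()}:
                cname = f"c_{len(const_names) + 1}"
            const_names[c] = cname
            params.append(Parameter(cname, role="constant", value=c))
    for g in groups:
        dP = param_name("dP", g.label)
        dA = param_name("dA", g.label)
        b = param_name("b", g.label)
        gg = param_name("g", g.label)
        params += [Parameter(dP), Parameter(dA), Parameter(b), Parameter(gg)]
        c = const_names[g.constant]

        present = Tree(
            name=tree_name(g.label, PRESENT),
            categories=CATEGORIES,
            branches=(
                Branch((Factor(dP),), "suspect_id"),
                Branch((Factor(dP, True), Factor(b)), "suspect_id"),
                Branch(
                    (Factor(dP, True), Factor(b, True), Factor(gg), Factor(c)),
                    "suspect_id",
                ),
                Branch(
                    (Factor(dP, True), Factor(b, True), Factor(gg), Factor(c, True)),
                    "filler_id",
                ),
                Branch(
                    (Factor(dP, True), Factor(b, True), Factor(gg, True)),
                    "rejection",
                ),
            ),
        )
        absent = Tree(
            name=tree_name(g.label, ABSENT),
            categories=CATEGORIES,
            branches=(
                Branch((Factor(dA, True), Factor(b)), "suspect_id"),
                Branch(
                    (Factor(dA, True), Factor(b, True), Factor(gg), Factor(c)),
                    "suspect_id",
                ),
                Branch(
                    (Factor(dA, True), Factor(b, True), Factor(gg), Factor(c, True)),
                    "filler_id",
                ),
                Branch((Factor(dA),), "rejection"),
                Branch(
                    (Factor(dA, True), Factor(b, True), Factor(gg, True)),
                    "rejection",
                ),
            ),
        )
        trees += [present, absent]
    return MptModel(trees, params)


def base_restrictions(groups: Sequence[GroupSpec]) -> RestrictionSet:
    """Equate b and dA across all groups (classes of size 1 are dropped)."""
    bs = frozenset(param_name("b", g.label) for g in groups)
    das = frozenset(param_name("dA", g.label) for g in groups)
    return RestrictionSet(equalities=[c for c in (bs, das) if len(c) > 1])


@dataclass(frozen=True)
class HypothesisTestPlan:
    """One df-1 nested test: equate ``target`` (dP or g) across the two
    groups that differ on ``contrast`` inside stratum ``stratum``.

    contrast "size" compares lineup sizes within an instruction condition
    (stratum "low" or "neutral"); contrast "instruction" compares
    instruction conditions within a lineup size (stratum "three" or "six",
    i.e. a lineup-size label prefix).
    """

    target: str
    contrast: str
    stratum: str

    def __post_init__(self) -> None:
        if self.target not in ("dP", "g"):
            raise ValueError("target must be 'dP' or 'g'")
        if self.contrast not in ("size", "instruction"):
            raise ValueError("contrast must be 'size' or 'instruction'")

    def parameter_pair(self, groups: Sequence[GroupSpec]) -> tuple[str, str]:
        if self.contrast == "size":
            sel = [g for g in groups if g.instruction == self.stratum]
            key = lambda g: g.lineup_size
        else:
            sel = [
                g
                for g in groups
                if _size_word(g.lineup_size) == self.stratum
                or str(g.lineup_size) == self.stratum
            ]
            key = lambda g: g.instruction
        if len(sel) != 2 or key(sel[0]) == key(sel[1]):
            raise MptError(
                f"stratum {self.stratum!r} does not select exactly two "
                f"groups differing on {self.contrast}"
            )
        sel = sorted(sel, key=key)
        return tuple(param_name(self.target, g.label) for g in sel)

    def describe(self) -> str:
        within = {"size": "instructions", "instruction": "lineup size"}[
            self.contrast
        ]
        return (
            f"{self.target} equal across {self.contrast} "
            f"({within} = {self.stratum})"
        )


def _size_word(n: int) -> str:
    return {3: "three", 6: "six"}.get(n, str(n))


def default_plans() -> list[HypothesisTestPlan]:
    """The eight published tests, in reporting order: dP across size within
    each instruction, g across size within each instruction, g across
    instructions within each size, dP across instructions within each size.
    """
    return [
        HypothesisTestPlan("dP", "size", LOW),
        HypothesisTestPlan("dP", "size", NEUTRAL),
        HypothesisTestPlan("g", "size", LOW),
        HypothesisTestPlan("g", "size", NEUTRAL),
        HypothesisTestPlan("g", "instruction", "three"),
        HypothesisTestPlan("g", "instruction", "six"),
        HypothesisTestPlan("dP", "instruction", "three"),
        HypothesisTestPlan("dP", "instruction", "six"),
    ]


@dataclass
class NestedTestResult:
    plan: HypothesisTestPlan
    delta_g2: float
    df: int
    p: float
    restricted: FitResult


@dataclass
class ModelAnalysis:
    groups: list[GroupSpec]
    base: FitResult
    tests: list[NestedTestResult] = field(default_factory=list)


def run_model_analysis(
    freqs: FrequencyTable,
    plans: Sequence[HypothesisTestPlan] | None = None,
    groups: Sequence[GroupSpec] | None = None,
    options: FitOptions | None = None,
) -> ModelAnalysis:
    """Fit the joint base model, then each plan's restricted model from a
    fresh multistart, and report the chi-square ΔG² (df = 1) per plan."""
    groups = list(groups) if groups is not None else study_groups()
    plans = list(plans) if plans is not None else default_plans()
    model = build_joint_model(groups)
    base_rs = base_restrictions(groups)
    for g in groups:
        for lt in (PRESENT, ABSENT):
            if tree_name(g.label, lt) not in freqs.counts:
                raise MptError(f"frequency table lacks tree {tree_name(g.label, lt)!r}")
    base = fit(model, freqs, base_rs, options)
    tests: list[NestedTestResult] = []
    for plan in plans:
        pair = plan.parameter_pair(groups)
        restricted = fit(model, freqs, base_rs.with_equality(pair), options)
        delta = max(restricted.g2 - base.g2, 0.0)
        ddf = restricted.df - base.df
        tests.append(
            NestedTestResult(
                plan=plan,
                delta_g2=delta,
                df=ddf,
                p=float(chi2.sf(delta, ddf)),
                restricted=restricted,
            )
        )
    return ModelAnalysis(groups=groups, base=base, tests=tests)
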