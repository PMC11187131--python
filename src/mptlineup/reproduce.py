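"""End-to-end reproduction of the published analyses from the packaged
Table-of-frequencies fixtures: base-model fit, parameter tables, nested
restriction tests, observable-rate z-tests, and the design sensitivity.

Every computed statistic is paired with the published value and a match
flag at the published rounding (half-up).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal

from . import fixtures
from .inference import SensitivitySpec, sensitivity_w
from .lineup import (
    ABSENT,
    PRESENT,
    default_plans,
    run_model_analysis,
    tree_name,
)
from .mpt import FitOptions
from .rates import two_proportion_z

# Published reference values keyed by experiment. Nested-test and estimate
# orders follow default_plans() and study_groups().
_REFERENCE = {
    "exp1": {
        "base_g2": 8.04, "base_df": 6, "base_p": 0.235,
        "dP": [0.31, 0.37, 0.15, 0.19],
        "dP_se": [0.03, 0.03, 0.02, 0.03],
        "g": [0.39, 0.59, 0.49, 0.68],
        "g_se": [0.02, 0.02, 0.02, 0.02],
        "b": 0.04, "b_se": 0.01, "dA": 0.03, "dA_se": 0.03,
        "delta_g2": [21.04, 20.12, 15.42, 12.81, 52.24, 55.75, 2.27, 1.95],
        "delta_p": [None, None, None, None, None, None, 0.132, 0.162],
        "z_innocent": 0.12, "p_innocent": 0.904,
        "z_culprit": 3.57, "p_culprit": None,  # printed as < 0.001
        "w": 0.06,
    },
    "exp2": {
        "base_g2": 3.40, "base_df": 6, "base_p": 0.757,
        "dP": [0.33, 0.37, 0.21, 0.28],
        "dP_se": [0.03, 0.03, 0.02, 0.03],
        "g": [0.30, 0.45, 0.29, 0.45],
        "g_se": [0.02, 0.02, 0.02, 0.02],
        "b": 0.05, "b_se": 0.01, "dA": 0.04, "dA_se": 0.05,
        "delta_g2": [11.97, 6.89, 0.22, 0.06, 28.81, 42.21, 1.18, 3.72],
        "delta_p": [None, 0.009, 0.637, 0.815, None, None, 0.278, 0.054],
        "z_innocent": 1.53, "p_innocent": 0.126,
        "z_culprit": 2.14, "p_culprit": 0.032,
        "w": 0.06,
    },
}


def round_half_up(x: float, decimals: int) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ReportLine:
    label: str
    computed: float
    reference: float | None
    decimals: int
    matches: bool

    @staticmethod
    def compare(label: str, computed: float, reference: float | None, decimals: int,
                below: bool = False) -> "ReportLine":
        """A reference of None with below=True means 'printed as < 0.001'."""
        if below:
            ok = computed < 10.0 ** (-decimals)
            return ReportLine(label, computed, None, decimals, ok)
        ok = round_half_up(computed, decimals) == reference
        return ReportLine(label, computed, reference, decimals, ok)


@dataclass
class ReproductionReport:
    experiment: str
    lines: list[ReportLine] = field(default_factory=list)

    @property
    def all_match(self) -> bool:
        return all(ln.matches for ln in self.lines)

    def to_json(self) -> str:
        return json.dumps(
            {
                "experiment": self.experiment,
                "all_match": self.all_match,
                "lines": [asdict(ln) for ln in self.lines],
            },
            indent=2,
        )

    def to_markdown(self) -> str:
        out = [
            f"# Reproduction report: {self.experiment}",
            "",
            "| statistic | computed | published | match |",
            "|---|---|---|---|",
        ]
        for ln in self.lines:
            ref = f"< {10.0 ** (-ln.decimals):g}" if ln.reference is None else (
                f"{ln.reference:.{ln.decimals}f}"
            )
            out.append(
                f"| {ln.label} | {ln.computed:.{max(ln.decimals, 3)}f} | {ref} | "
                f"{'yes' if ln.matches else 'NO'} |"
            )
        out.append("")
        out.append(f"All statistics match: {'yes' if self.all_match else 'NO'}")
        return "\n".join(out)


def reproduce(experiment: str, options: FitOptions | None = None) -> ReproductionReport:
    """Run the full pipeline on a packaged fixture and compare every
    statistic against its published value at printed precision."""
    if experiment not in _REFERENCE:
        raise KeyError(
            f"unknown experiment {experiment!r}; available: "
            f"{', '.join(sorted(_REFERENCE))}"
        )
    ref = _REFERENCE[experiment]
    groups, freqs = fixtures.fixture(experiment)
    analysis = run_model_analysis(freqs, default_plans(), groups, options)
    rep = ReproductionReport(experiment=experiment)
    add = rep.lines.append
    cmp = ReportLine.compare

    base = analysis.base
    add(cmp("base G2(6)", base.g2, ref["base_g2"], 2))
    add(ReportLine("base df", base.df, ref["base_df"], 0, base.df == ref["base_df"]))
    add(cmp("base p", base.p, ref["base_p"], 3))

    for i, g in enumerate(groups):
        for par in ("dP", "g"):
            name = f"{par}_{g.label}"
            add(cmp(f"{par} ({g.label})", base.estimates[name], ref[par][i], 2))
            add(cmp(
                f"SE {par} ({g.label})",
                base.standard_errors[name],
                ref[f"{par}_se"][i],
                2,
            ))
    b_name = f"b_{groups[0].label}"
    dA_name = f"dA_{groups[0].label}"
    add(cmp("b", base.estimates[b_name], ref["b"], 2))
    add(cmp("SE b", base.standard_errors[b_name], ref["b_se"], 2))
    add(cmp("dA", base.estimates[dA_name], ref["dA"], 2))
    add(cmp("SE dA", base.standard_errors[dA_name], ref["dA_se"], 2))

    for test, dg2, p_ref in zip(analysis.tests, ref["delta_g2"], ref["delta_p"]):
        add(cmp(f"dG2(1): {test.plan.describe()}", test.delta_g2, dg2, 2))
        add(cmp(
            f"p: {test.plan.describe()}", test.p, p_ref, 3, below=p_ref is None
        ))

    # Observable rates: three-person/low-culprit-probability vs the
    # six-person/neutral standard of comparison; |z| compared at 2 dp.
    fa = freqs.counts[tree_name("three_low", ABSENT)]["suspect_id"]
    fb = freqs.counts[tree_name("six_neutral", ABSENT)]["suspect_id"]
    na = freqs.total(tree_name("three_low", ABSENT))
    nb = freqs.total(tree_name("six_neutral", ABSENT))
    t_inn = two_proportion_z(fa, na, fb, nb)
    add(cmp("|z| innocent-suspect ids", abs(t_inn.z), ref["z_innocent"], 2))
    add(cmp("p innocent-suspect ids", t_inn.p, ref["p_innocent"], 3))

    ca = freqs.counts[tree_name("three_low", PRESENT)]["suspect_id"]
    cb = freqs.counts[tree_name("six_neutral", PRESENT)]["suspect_id"]
    ma = freqs.total(tree_name("three_low", PRESENT))
    mb = freqs.total(tree_name("six_neutral", PRESENT))
    t_cul = two_proportion_z(ca, ma, cb, mb)
    add(cmp("|z| culprit ids", abs(t_cul.z), ref["z_culprit"], 2))
    add(cmp(
        "p culprit ids", t_cul.p, ref["p_culprit"], 3,
        below=ref["p_culprit"] is None,
    ))

    sens = sensitivity_w(SensitivitySpec(
        alpha=0.05, beta=0.05, df=1,
        n_responses=fixtures.N_PARTICIPANTS[experiment]
        * fixtures.RESPONSES_PER_PARTICIPANT,
    ))
    add(cmp("sensitivity w", sens.w, ref["w"], 2))
    return rep
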