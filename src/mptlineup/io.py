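"""Readers and writers: frequency CSV, EQN model files, restriction YAML.

Frequency CSV columns are ``group, tree, category, count``; internally a
tree belonging to a group is keyed ``"<group>.<tree>"`` (an empty group
column leaves the tree name as is). Category order follows first
appearance, which for the packaged writers is always (suspect/culprit
identification, filler identification, rejection).

The EQN dialect is the community MPT text format: a header line with the
number of branch lines, then ``tree category term`` lines where a term is
a ``*``-separated product of parameter names, complements written
``(1-name)``, and numeric constants. Categories belong to exactly one
tree.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd
import yaml

from .mpt import (
    Branch,
    Factor,
    FrequencyTable,
    MptError,
    MptModel,
    Parameter,
    RestrictionSet,
    Tree,
)


class ParseError(MptError):
    pass


# ---------------------------------------------------------------------------
# Frequency CSV
# ---------------------------------------------------------------------------


def _tree_key(group, tree) -> str:
    group = "" if group is None or (isinstance(group, float) and pd.isna(group)) else str(group)
    return f"{group}.{tree}" if group else str(tree)


def read_frequency_csv(path: str | Path) -> FrequencyTable:
    df = pd.read_csv(path, dtype=str, comment="#")
    required = {"tree", "category", "count"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"missing column(s): {sorted(missing)}")
    counts: dict[str, dict[str, int]] = {}
    for i, row in df.iterrows():
        try:
            n = int(row["count"])
        except (TypeError, ValueError):
            raise ParseError(f"row {i + 2}: count {row['count']!r} is not an integer")
        if n < 0:
            raise ParseError(f"row {i + 2}: negative count {n}")
        key = _tree_key(row.get("group"), row["tree"])
        cats = counts.setdefault(key, {})
        if row["category"] in cats:
            raise ParseError(
                f"row {i + 2}: duplicate cell {key!r}/{row['category']!r}"
            )
        cats[row["category"]] = n
    if not counts:
        raise ParseError("empty frequency table")
    ncats = {len(c) for c in counts.values()}
    if len(ncats) > 1:
        raise ParseError("trees disagree on their number of categories")
    return FrequencyTable(counts)


def write_frequency_csv(freqs: FrequencyTable, path: str | Path) -> None:
    rows = []
    for tree, cats in freqs.counts.items():
        group, _, local = tree.rpartition(".")
        for cat, n in cats.items():
            rows.append({"group": group, "tree": local, "category": cat, "count": n})
    pd.DataFrame(rows, columns=["group", "tree", "category", "count"]).to_csv(
        path, index=False
    )


# ---------------------------------------------------------------------------
# EQN model files
# ---------------------------------------------------------------------------

_COMPLEMENT = re.compile(r"^\(1\s*-\s*([^)]+)\)$")
_NUMBER = re.compile(r"^\d*\.?\d+$")


def _parse_factor(token: str) -> Factor:
    token = token.strip()
    m = _COMPLEMENT.match(token)
    complement = False
    if m:
        token, complement = m.group(1).strip(), True
    if _NUMBER.match(token):
        return Factor(float(token), complement)
    if not re.match(r"^[A-Za-z_][A-Za-z0-9_.]*$", token):
        raise ParseError(f"cannot parse factor {token!r}")
    return Factor(token, complement)


def parse_eqn(text: str) -> MptModel:
    """Parse an EQN model description into an MptModel.

    All names appearing in terms become free parameters; numeric literals
    stay literal constants.
    """
    lines = [
        ln.strip()
        for ln in text.splitlines()
        if ln.strip() and not ln.lstrip().startswith("#")
    ]
    if not lines:
        raise ParseError("empty EQN text")
    try:
        declared = int(lines[0])
        body = lines[1:]
    except ValueError:
        declared = None
        body = lines
    if declared is not None and declared != len(body):
        raise ParseError(
            f"header declares {declared} branch lines, found {len(body)}"
        )

    tree_cats: dict[str, list[str]] = {}
    tree_branches: dict[str, list[Branch]] = {}
    cat_owner: dict[str, str] = {}
    names: set[str] = set()
    for ln in body:
        parts = ln.split(None, 2)
        if len(parts) != 3:
            raise ParseError(f"malformed line: {ln!r}")
        tree, cat, term = parts
        if cat in cat_owner and cat_owner[cat] != tree:
            raise ParseError(
                f"category {cat!r} appears in trees {cat_owner[cat]!r} and {tree!r}"
            )
        cat_owner[cat] = tree
        factors = tuple(_parse_factor(tok) for tok in term.split("*"))
        for f in factors:
            if isinstance(f.ref, str):
                names.add(f.ref)
        cats = tree_cats.setdefault(tree, [])
        if cat not in cats:
            cats.append(cat)
        tree_branches.setdefault(tree, []).append(Branch(factors, cat))

    trees = [
        Tree(name, tuple(tree_cats[name]), tuple(tree_branches[name]))
        for name in tree_cats
    ]
    return MptModel(trees, [Parameter(n) for n in sorted(names)])


def _factor_str(model: MptModel, f: Factor) -> str:
    if isinstance(f.ref, str):
        p = model.parameters[f.ref]
        base = f"{p.value:.5f}" if p.role == "constant" else f.ref
    else:
        base = f"{float(f.ref):.5f}"
    return f"(1-{base})" if f.complement else base


def emit_eqn(model: MptModel) -> str:
    """Render a model as EQN text; categories are tree-qualified so that
    every category belongs to exactly one tree. Named constants are
    emitted as their 5-decimal values."""
    lines = []
    for tree in model.trees:
        for br in tree.branches:
            term = "*".join(_factor_str(model, f) for f in br.factors)
            lines.append(f"{tree.name} {tree.name}.{br.category} {term}")
    return "\n".join([str(len(lines))] + lines) + "\n"


# ---------------------------------------------------------------------------
# Restriction YAML
# ---------------------------------------------------------------------------


def read_restrictions_yaml(path: str | Path) -> RestrictionSet:
    """YAML with optional keys ``equal`` (list of name lists) and ``fix``
    (name -> value mapping)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    equal = [frozenset(map(str, cls)) for cls in data.get("equal", [])]
    fixed = {str(k): float(v) for k, v in (data.get("fix") or {}).items()}
    return RestrictionSet(equalities=equal, fixed=fixed)
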