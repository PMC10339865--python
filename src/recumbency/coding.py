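"""Two-observer binary ethogram: agreement, consensus, class composition.

Each sampled image is coded 0 (every animal in the group recumbent,
sternal or lateral) or 1 (at least one animal standing or sitting) by two
independent observers.  Discrepant codes are resolved by discussion; that
adjudication is an explicit input table here, since a human consensus
cannot be computed.  A pig lying on top of others in a possibly
half-standing posture is coded 0 by labeling convention — a documentation
rule with no computational counterpart.
"""

from __future__ import annotations

import pandas as pd

KEY = ["pen_id", "t_s"]


def _keyed_codes(table: pd.DataFrame, name: str) -> pd.Series:
    for col in KEY + ["code"]:
        if col not in table.columns:
            raise ValueError(f"{name} table missing column {col!r}")
    if table.duplicated(subset=KEY).any():
        raise ValueError(f"{name} table has duplicate (pen_id, t_s) keys")
    s = table.set_index(KEY)["code"]
    if not s.isin([0, 1]).all():
        raise ValueError(f"{name} table has codes outside {{0, 1}}")
    return s


def intercoder_agreement(codes_a: pd.DataFrame, codes_b: pd.DataFrame) -> float:
    """Percentage of (pen, timestamp) keys coded identically by both observers.

    Both tables must cover exactly the same keys; a mismatch is rejected
    with the differing keys listed.
    """
    a = _keyed_codes(codes_a, "coder A")
    b = _keyed_codes(codes_b, "coder B")
    if not a.index.equals(b.index):
        only_a = a.index.difference(b.index)
        only_b = b.index.difference(a.index)
        raise ValueError(
            "coder tables cover different keys; "
            f"only in A: {list(only_a[:5])}, only in B: {list(only_b[:5])}"
        )
    return float(100.0 * (a == b).mean())


def build_consensus(
    codes_a: pd.DataFrame,
    codes_b: pd.DataFrame,
    resolution: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Merge two coder tables into consensus labels.

    Keys on which the coders agree pass through unchanged.  Discrepant
    keys take the adjudicated code from ``resolution`` (columns pen_id,
    t_s, code) and are flagged ``was_discrepant``; any discrepancy without
    an adjudication is an error.
    """
    a = _keyed_codes(codes_a, "coder A")
    b = _keyed_codes(codes_b, "coder B")
    if not a.index.equals(b.index):
        raise ValueError("coder tables cover different keys")
    discrepant = a != b
    codes = a.copy()
    if discrepant.any():
        if resolution is None:
            raise ValueError(
                f"{int(discrepant.sum())} coding discrepancies but no resolution table"
            )
        res = _keyed_codes(resolution, "resolution")
        unresolved = a.index[discrepant].difference(res.index)
        if len(unresolved):
            raise ValueError(
                f"unresolved coding discrepancies at keys {list(unresolved[:5])}"
            )
        codes[discrepant] = res.loc[a.index[discrepant]]
    out = codes.rename("code").reset_index()
    out["was_discrepant"] = discrepant.to_numpy()
    return out


def class_composition(labels: pd.DataFrame) -> pd.DataFrame:
    """Per-pen counts of standing (1) and recumbent (0) labels, plus totals.

    Returns a frame indexed by pen_id with columns ``standing`` and
    ``recumbent`` and a final ``Total`` row.
    """
    if labels.empty:
        raise ValueError("no labels")
    _keyed_codes(labels, "labels")
    counts = (
        labels.groupby("pen_id")["code"]
        .agg(standing=lambda c: int((c == 1).sum()), recumbent=lambda c: int((c == 0).sum()))
    )
    counts.loc["Total"] = counts.sum()
    return counts.astype(int)


def standing_fraction_pct(labels: pd.DataFrame) -> float:
    """Share of labels coded 1 (some animal standing), in percent."""
    comp = class_composition(labels)
    total = comp.loc["Total"]
    return float(100.0 * total["standing"] / (total["standing"] + total["recumbent"]))
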