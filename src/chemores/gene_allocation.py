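"""Allocate significant genes to patient subgroups by fluctuation ranges.

A significant gene is *specific* to a resistant subgroup when its mean over
that subgroup's samples falls outside the sensitive group's fluctuation
range (mean +/- sd over all CR samples, by default); symmetrically, a gene
is *allocated* to a sensitive subgroup when its mean there falls outside
the pooled resistant group's range.  Genes may be specific to several
subgroups at once; the intersections over the resistant subgroups and over
all subgroups are both reported.

An alternative reading of the fluctuation range — the span (min..max) of
the opposite group's per-subgroup means — is available via ``mode="span"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import InputError
from .subgrouping import SubgroupModel, summarize_subgroups

__all__ = ["GeneAllocation", "group_fluctuation_range", "allocate_genes", "allocation_to_frame"]


@dataclass
class GeneAllocation:
    specific_to_resistant: dict[int, set[str]]
    allocated_to_sensitive: dict[int, set[str]]
    common_resistant: set[str] = field(default_factory=set)
    common_all: set[str] = field(default_factory=set)


def group_fluctuation_range(m: pd.DataFrame, samples, n_sd: float = 1.0) -> pd.DataFrame:
    """Per-gene [mean - n_sd*sd, mean + n_sd*sd] over the given samples."""
    samples = list(samples)
    if len(samples) < 2:
        raise InputError("fluctuation range requires >= 2 samples")
    sub = m[samples]
    mu = sub.mean(axis=1)
    sd = sub.std(axis=1, ddof=1)
    return pd.DataFrame({"low": mu - n_sd * sd, "high": mu + n_sd * sd})


def _span_of_means(m: pd.DataFrame, groups: dict[int, list[str]]) -> pd.DataFrame:
    means = pd.DataFrame({g: m[s].mean(axis=1) for g, s in groups.items()})
    return pd.DataFrame({"low": means.min(axis=1), "high": means.max(axis=1)})


def allocate_genes(
    degs,
    m: pd.DataFrame,
    model: SubgroupModel,
    ann: pd.DataFrame,
    mode: str = "mean_sd",
    n_sd: float = 1.0,
) -> GeneAllocation:
    """Assign significant genes to subgroups by the fluctuation-range rule."""
    if mode not in ("mean_sd", "span"):
        raise InputError(f"unknown fluctuation-range mode {mode!r}")
    degs = [g for g in degs]
    missing = [g for g in degs if g not in m.index]
    if missing:
        raise InputError(f"genes absent from matrix: {missing[:5]}")
    if model.summary is None:
        summarize_subgroups(model, ann)
    res_subs = model.resistant_subgroups
    sens_subs = [s for s in model.summary.index if s not in res_subs]
    if not res_subs or not sens_subs:
        raise InputError("model must distinguish >= 1 resistant and >= 1 sensitive subgroup")
    for sub in model.summary.index:
        if model.summary.loc[sub, "size"] < 1:
            raise InputError(f"subgroup {sub} is empty")

    sub_m = m.loc[degs]
    resp = ann.loc[m.columns, "response"]
    cr_samples = resp.index[resp == "CR"].tolist()
    nocr_samples = resp.index[resp == "NOCR"].tolist()
    groups = {int(s): model.samples_of(s) for s in model.summary.index}

    if mode == "mean_sd":
        sens_range = group_fluctuation_range(sub_m, cr_samples, n_sd=n_sd)
        res_range = group_fluctuation_range(sub_m, nocr_samples, n_sd=n_sd)
    else:
        sens_range = _span_of_means(sub_m, {s: groups[s] for s in sens_subs})
        res_range = _span_of_means(sub_m, {s: groups[s] for s in res_subs})

    def outside(means: pd.Series, rng: pd.DataFrame) -> pd.Series:
        return (means < rng["low"]) | (means > rng["high"])

    specific = {
        int(s): set(sub_m.index[outside(sub_m[groups[s]].mean(axis=1), sens_range)])
        for s in res_subs
    }
    to_sensitive = {
        int(s): set(sub_m.index[outside(sub_m[groups[s]].mean(axis=1), res_range)])
        for s in sens_subs
    }
    common_resistant = set.intersection(*specific.values()) if specific else set()
    all_sets = list(specific.values()) + list(to_sensitive.values())
    common_all = set.intersection(*all_sets) if all_sets else set()
    return GeneAllocation(
        specific_to_resistant=specific,
        allocated_to_sensitive=to_sensitive,
        common_resistant=common_resistant,
        common_all=common_all,
    )


def allocation_to_frame(alloc: GeneAllocation) -> pd.DataFrame:
    """Long-format (gene_id, subgroup, side, is_common) table."""
    rows = []
    for sub in sorted(alloc.specific_to_resistant):
        for g in sorted(alloc.specific_to_resistant[sub]):
            rows.append((g, sub, "resistant", g in alloc.common_resistant))
    for sub in sorted(alloc.allocated_to_sensitive):
        for g in sorted(alloc.allocated_to_sensitive[sub]):
            rows.append((g, sub, "sensitive", g in alloc.common_resistant))
    return pd.DataFrame(rows, columns=["gene_id", "subgroup", "side", "is_common"])
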