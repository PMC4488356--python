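"""Hypergeometric gene-set enrichment and pathway deviation scores.

Enrichment of a query gene set against a pathway collection uses the
upper-tail hypergeometric probability P(X >= k) with population = the
gene universe, successes = the pathway's genes in the universe, and
draws = the query; Benjamini-Hochberg q-values are reported alongside.

The per-(pathway, subgroup) deviation score is

    A(P) = log10( (1/N) * sum_i (Xbar_i - Ybar_i)^2 )

over the pathway's N differentially expressed genes, where Xbar_i is the
gene's mean in the scored subgroup and Ybar_i its mean over all sensitive
samples.  A zero mean-squared deviation leaves the score undefined (NaN).
The prose variant without the 1/N factor is available via
``variant="sum"``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .subgrouping import SubgroupModel

__all__ = [
    "hypergeom_enrichment",
    "bh_fdr",
    "pathway_deviation_score",
    "deviation_profile",
    "significant_pathways",
]


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(
    query, universe, pathways: dict[str, set[str]], alpha: float = 0.05
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``query`` in each pathway.

    Pathways are intersected with the universe before testing; the query
    must be a subset of the universe.  Returns a DataFrame sorted by
    p-value with columns pathway, pathway_size, count, p_value, q_value,
    significant (p < alpha).
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise InputError(f"query genes outside the universe: {offenders[:10]}")
    M, nq = len(universe), len(query)
    rows = []
    for name in sorted(pathways):
        in_universe = pathways[name] & universe
        k = len(in_universe & query)
        p = float(hypergeom.sf(k - 1, M, len(in_universe), nq))
        rows.append({"pathway": name, "pathway_size": len(in_universe), "count": k, "p_value": p})
    out = pd.DataFrame(rows)
    if out.empty:
        raise InputError("no pathways to test")
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha
    return out.sort_values(["p_value", "pathway"], kind="mergesort").reset_index(drop=True)


def pathway_deviation_score(
    pathway_genes,
    subgroup_samples,
    sensitive_samples,
    m: pd.DataFrame,
    variant: str = "mean",
) -> tuple[float, int]:
    """Deviation score A(P) and gene count N for one pathway in one subgroup."""
    if variant not in ("mean", "sum"):
        raise InputError(f"unknown deviation-score variant {variant!r}")
    genes = [g for g in m.index if g in set(pathway_genes)]
    if not genes:
        raise InputError("no pathway genes present in the expression matrix")
    subgroup_samples = list(subgroup_samples)
    sensitive_samples = list(sensitive_samples)
    if not subgroup_samples or not sensitive_samples:
        raise InputError("both sample sets must be nonempty")
    d = m.loc[genes, subgroup_samples].mean(axis=1) - m.loc[genes, sensitive_samples].mean(axis=1)
    sq = (d**2).to_numpy()
    val = sq.mean() if variant == "mean" else sq.sum()
    A = float(np.log10(val)) if val > 0 else float("nan")
    return A, len(genes)


def significant_pathways(enrichment_tables) -> list[str]:
    """Union (sorted) of significantly enriched pathway names across tables."""
    names: set[str] = set()
    for table in enrichment_tables:
        names |= set(table.loc[table["significant"], "pathway"])
    return sorted(names)


def deviation_profile(
    pathways: dict[str, set[str]],
    pathway_names,
    deg_genes,
    model: SubgroupModel,
    ann: pd.DataFrame,
    m: pd.DataFrame,
    variant: str = "mean",
) -> pd.DataFrame:
    """Pathway-by-subgroup deviation score table.

    Each pathway is scored with its differentially expressed genes
    (pathway ∩ ``deg_genes`` ∩ matrix rows) in every subgroup of the model,
    against the mean over all sensitive (CR) samples.  Pathways with no
    scorable genes yield NaN rows with n_genes = 0.
    """
    deg_set = set(deg_genes) & set(m.index)
    resp = ann.loc[m.columns, "response"]
    sensitive = resp.index[resp == "CR"].tolist()
    if not sensitive:
        raise InputError("no sensitive (CR) samples in the matrix")
    subs = sorted(model.assignment.unique())
    rows = []
    for name in pathway_names:
        genes = pathways[name] & deg_set
        row: dict[str, object] = {"pathway": name, "n_genes": len(genes)}
        for sub in subs:
            col = f"subgroup_{sub}"
            if genes:
                A, _ = pathway_deviation_score(genes, model.samples_of(sub), sensitive, m, variant)
            else:
                A = float("nan")
            row[col] = A
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway")
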