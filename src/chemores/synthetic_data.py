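"""Seeded synthetic cohorts with planted ground truth.

The generator emulates the statistical structure of a two-phenotype
(chemo-sensitive CR vs chemo-resistant NOCR) log-expression cohort after
normalization: per-gene Gaussian baseline noise, a set of genes shifted in
*all* resistant samples (common differential expression), sets shifted only
within one latent resistant subgroup (subgroup-specific differential
expression), and disjoint marker sets shifted within each latent sensitive
subgroup so that clustering can also split the CR patients.  Shift signs
are random per gene so both up- and downregulation occur.

Companion generators produce a GMT-style pathway collection with planted
enriched pathways and an undirected interaction network with planted hub
genes, so every downstream stage has a recoverable ground truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_io
from .errors import ConfigError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_pathways",
    "generate_network",
    "write_cohort",
]


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic cohort.

    Cohort sizes default to the basal-like discovery cohort (24 sensitive,
    22 resistant) with two latent subgroups on each side.  Effect sizes are
    expressed in units of the baseline noise standard deviation.
    """

    n_genes: int = 500
    n_sensitive: int = 24
    n_resistant: int = 22
    k_resistant_subgroups: int = 2
    k_sensitive_subgroups: int = 2
    n_common_de: int = 60
    n_specific_de_per_subgroup: int = 40
    n_sensitive_marker_per_subgroup: int = 40
    effect_size: float = 2.0
    noise_sd: float = 1.0
    n_pathways: int = 20
    pathway_size: int = 20
    n_planted_pathways_per_subgroup: int = 1
    n_hubs: int = 3
    hub_degree: int = 32
    background_edge_prob: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_sensitive": self.n_sensitive,
            "n_resistant": self.n_resistant,
            "k_resistant_subgroups": self.k_resistant_subgroups,
            "k_sensitive_subgroups": self.k_sensitive_subgroups,
            "n_common_de": self.n_common_de,
            "n_specific_de_per_subgroup": self.n_specific_de_per_subgroup,
            "n_sensitive_marker_per_subgroup": self.n_sensitive_marker_per_subgroup,
            "n_pathways": self.n_pathways,
            "pathway_size": self.pathway_size,
            "n_planted_pathways_per_subgroup": self.n_planted_pathways_per_subgroup,
            "n_hubs": self.n_hubs,
            "hub_degree": self.hub_degree,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigError(f"{name} must be >= 0, got {value}")
        if self.effect_size < 0:
            raise ConfigError("effect_size must be >= 0")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if not 0.0 <= self.background_edge_prob <= 1.0:
            raise ConfigError("background_edge_prob must lie in [0, 1]")
        budget = (
            self.n_common_de
            + self.k_resistant_subgroups * self.n_specific_de_per_subgroup
            + self.k_sensitive_subgroups * self.n_sensitive_marker_per_subgroup
        )
        if budget > self.n_genes:
            raise ConfigError(
                f"planted gene sets need {budget} genes but n_genes={self.n_genes}"
            )
        if self.n_sensitive < 2:
            raise ConfigError("n_sensitive must be >= 2 (normal range needs two samples)")
        if self.n_resistant < 1:
            raise ConfigError("n_resistant must be >= 1")
        if self.k_resistant_subgroups < 1 or self.k_sensitive_subgroups < 1:
            raise ConfigError("subgroup counts must be >= 1")


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort.

    ``specific_de_genes`` and ``sensitive_marker_genes`` are keyed by the
    planted subgroup labels (``R1..Rm``, ``S1..Sn``); all planted gene sets
    are pairwise disjoint.  ``planted_pathways`` and ``hub_genes`` are
    filled by :func:`generate_pathways` / :func:`generate_network`.
    """

    genes: list[str]
    common_de_genes: set[str]
    specific_de_genes: dict[str, set[str]]
    sensitive_marker_genes: dict[str, set[str]]
    sample_subgroup: dict[str, str]
    shift_sign: dict[str, int]
    planted_pathways: dict[str, list[str]] = field(default_factory=dict)
    planted_pathway_genes: dict[str, set[str]] = field(default_factory=dict)
    hub_genes: set[str] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        """All genes differentially expressed in resistant samples."""
        out = set(self.common_de_genes)
        for s in self.specific_de_genes.values():
            out |= s
        return out


def _split_subgroups(ids: list[str], k: int, prefix: str) -> dict[str, list[str]]:
    chunks = np.array_split(np.arange(len(ids)), k)
    return {f"{prefix}{j + 1}": [ids[i] for i in chunk] for j, chunk in enumerate(chunks)}


def generate_cohort(
    cfg: SyntheticConfig,
    truth: GroundTruth | None = None,
    cohort: str = "discovery",
    sample_prefix: str = "",
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate (expression, annotation, ground truth) for one cohort.

    When ``truth`` is given, its gene roles and shift signs are reused so a
    second (validation) cohort shares the planted biology but has fresh
    sampling noise; only ``cfg.seed`` controls the noise stream.  The
    planted subgroup of every sample is recorded in the annotation column
    ``planted_subgroup`` (and in ``truth.sample_subgroup`` for the cohort
    that created the truth object).
    """
    cfg.validate()
    rng_roles = np.random.default_rng([cfg.seed, 101])
    rng_noise = np.random.default_rng([cfg.seed, 202])

    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]
    sens_ids = [f"{sample_prefix}SEN{i:02d}" for i in range(cfg.n_sensitive)]
    res_ids = [f"{sample_prefix}RES{i:02d}" for i in range(cfg.n_resistant)]

    res_groups = _split_subgroups(res_ids, cfg.k_resistant_subgroups, "R")
    sens_groups = _split_subgroups(sens_ids, cfg.k_sensitive_subgroups, "S")
    sample_subgroup = {
        s: g for g, members in {**res_groups, **sens_groups}.items() for s in members
    }

    if truth is None:
        order = rng_roles.permutation(cfg.n_genes)
        cursor = 0

        def take(n: int) -> set[str]:
            nonlocal cursor
            out = {genes[i] for i in order[cursor : cursor + n]}
            cursor += n
            return out

        common = take(cfg.n_common_de)
        specific = {g: take(cfg.n_specific_de_per_subgroup) for g in sorted(res_groups)}
        markers = {g: take(cfg.n_sensitive_marker_per_subgroup) for g in sorted(sens_groups)}
        shifted = sorted(common | {x for s in specific.values() for x in s}
                         | {x for s in markers.values() for x in s})
        signs = {g: int(s) for g, s in zip(shifted, rng_roles.choice([-1, 1], len(shifted)))}
        truth = GroundTruth(
            genes=genes,
            common_de_genes=common,
            specific_de_genes=specific,
            sensitive_marker_genes=markers,
            sample_subgroup=sample_subgroup,
            shift_sign=signs,
        )

    cols = sens_ids + res_ids
    X = rng_noise.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, len(cols)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    col_pos = {s: j for j, s in enumerate(cols)}
    delta = cfg.effect_size * cfg.noise_sd

    def shift(gene_set: set[str], samples: list[str]) -> None:
        if not gene_set or not samples:
            return
        rows = [gene_pos[g] for g in sorted(gene_set)]
        js = [col_pos[s] for s in samples]
        sgn = np.array([truth.shift_sign[g] for g in sorted(gene_set)], dtype=float)
        X[np.ix_(rows, js)] += (sgn * delta)[:, None]

    shift(truth.common_de_genes, res_ids)
    for g, members in res_groups.items():
        shift(truth.specific_de_genes.get(g, set()), members)
    for g, members in sens_groups.items():
        shift(truth.sensitive_marker_genes.get(g, set()), members)

    expr = pd.DataFrame(X, index=pd.Index(genes, name="gene_id"), columns=cols)

    dss_res = rng_noise.uniform(0.5, 2.9, size=len(res_ids))
    dss_sens = rng_noise.uniform(3.2, 10.0, size=len(sens_ids))
    ann = pd.DataFrame(
        {
            "response": ["CR"] * len(sens_ids) + ["NOCR"] * len(res_ids),
            "subtype": "basal",
            "cohort": cohort,
            "planted_subgroup": [sample_subgroup[s] for s in cols],
            "dss_years": np.concatenate([dss_sens, dss_res]),
        },
        index=pd.Index(cols, name="sample_id"),
    )
    return expr, ann, truth


def generate_pathways(cfg: SyntheticConfig, truth: GroundTruth) -> dict[str, set[str]]:
    """Pathway collection with planted enriched pathways.

    Each planted pathway takes >=80% of its members from the corresponding
    resistant subgroup's specific genes and the rest from unshifted genes;
    background pathways are drawn uniformly from unshifted genes.  Pathway
    names are recorded in ``truth.planted_pathways``.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 303])
    shifted = truth.de_genes | {g for s in truth.sensitive_marker_genes.values() for g in s}
    null_pool = sorted(set(truth.genes) - shifted)

    n_de = math.ceil(0.8 * cfg.pathway_size)
    n_fill = cfg.pathway_size - n_de
    planted_total = cfg.n_planted_pathways_per_subgroup * len(truth.specific_de_genes)
    n_background = cfg.n_pathways - planted_total
    if n_background < 0:
        raise ConfigError(
            f"n_pathways={cfg.n_pathways} smaller than planted pathway count {planted_total}"
        )
    if cfg.pathway_size > len(null_pool):
        raise ConfigError(
            f"pathway_size={cfg.pathway_size} exceeds the {len(null_pool)} unshifted genes"
        )

    pathways: dict[str, set[str]] = {}
    truth.planted_pathways = {}
    truth.planted_pathway_genes = {}
    for sub in sorted(truth.specific_de_genes):
        pool = sorted(truth.specific_de_genes[sub])
        if n_de > len(pool):
            raise ConfigError(
                f"planted pathway needs {n_de} genes from subgroup {sub} "
                f"but only {len(pool)} specific genes exist"
            )
        names = []
        for t in range(cfg.n_planted_pathways_per_subgroup):
            members = set(rng.choice(pool, size=n_de, replace=False))
            members |= set(rng.choice(null_pool, size=n_fill, replace=False))
            name = f"PW_{sub}_{t + 1}"
            pathways[name] = members
            truth.planted_pathway_genes[name] = set(members)
            names.append(name)
        truth.planted_pathways[sub] = names
    for b in range(n_background):
        pathways[f"PW_BG{b + 1:02d}"] = set(
            rng.choice(null_pool, size=cfg.pathway_size, replace=False)
        )
    return pathways


def generate_network(cfg: SyntheticConfig, truth: GroundTruth) -> set[tuple[str, str]]:
    """Interaction network with planted hubs.

    Hubs are drawn from the common differentially expressed genes (falling
    back to the full DE pool if there are too few) and connected to
    ``hub_degree`` distinct DE genes; every other unordered gene pair is an
    edge independently with ``background_edge_prob``.  Hub identities are
    recorded in ``truth.hub_genes``.

    When pathways have already been planted, hub neighbors are drawn from
    the common DE genes plus the DE genes belonging to planted pathways —
    the candidate-and-common gene neighborhood that the biomarker stage
    restricts the network to; otherwise the full DE pool is used.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, 404])
    de_pool = sorted(truth.de_genes)
    if truth.planted_pathway_genes:
        candidate = set().union(*truth.planted_pathway_genes.values()) & truth.de_genes
        target_pool = sorted(truth.common_de_genes | candidate)
    else:
        target_pool = de_pool
    if cfg.n_hubs > 0 and cfg.hub_degree > len(target_pool) - 1:
        raise ConfigError(
            f"hub_degree={cfg.hub_degree} exceeds the {len(target_pool)} available DE genes"
        )
    hub_pool = sorted(truth.common_de_genes) if len(truth.common_de_genes) >= cfg.n_hubs else de_pool
    if cfg.n_hubs > len(hub_pool):
        raise ConfigError(f"n_hubs={cfg.n_hubs} exceeds the hub candidate pool {len(hub_pool)}")

    edges: set[tuple[str, str]] = set()
    hubs = sorted(rng.choice(hub_pool, size=cfg.n_hubs, replace=False)) if cfg.n_hubs else []
    for h in hubs:
        targets = [g for g in target_pool if g != h]
        chosen = rng.choice(targets, size=cfg.hub_degree, replace=False)
        for t in chosen:
            edges.add((h, t) if h < t else (t, h))

    if cfg.background_edge_prob > 0:
        n = len(truth.genes)
        iu, ju = np.triu_indices(n, k=1)
        mask = rng.random(iu.shape[0]) < cfg.background_edge_prob
        genes = truth.genes
        for i, j in zip(iu[mask], ju[mask]):
            a, b = genes[i], genes[j]
            edges.add((a, b) if a < b else (b, a))

    truth.hub_genes = set(hubs)
    return edges


def truth_to_frame(truth: GroundTruth) -> pd.DataFrame:
    """Long-format (gene, role, subgroup) table of the planted gene sets."""
    rows = []
    for g in sorted(truth.common_de_genes):
        rows.append((g, "common_de", ""))
    for sub in sorted(truth.specific_de_genes):
        for g in sorted(truth.specific_de_genes[sub]):
            rows.append((g, "specific_de", sub))
    for sub in sorted(truth.sensitive_marker_genes):
        for g in sorted(truth.sensitive_marker_genes[sub]):
            rows.append((g, "sensitive_marker", sub))
    for g in sorted(truth.hub_genes):
        rows.append((g, "hub", ""))
    return pd.DataFrame(rows, columns=["gene_id", "role", "subgroup"])


def write_cohort(
    outdir: str | Path,
    cfg: SyntheticConfig,
    expr: pd.DataFrame,
    ann: pd.DataFrame,
    truth: GroundTruth,
    pathways: dict[str, set[str]] | None = None,
    interactions: set[tuple[str, str]] | None = None,
) -> None:
    """Serialize a simulated cohort in the same formats :mod:`chemores.data_io` reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data_io.write_expression_matrix(expr, outdir / "expression.tsv")
    data_io.write_annotations(ann, outdir / "annotations.tsv")
    truth_to_frame(truth).to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
    if pathways is not None:
        data_io.write_gene_sets(pathways, outdir / "pathways.gmt")
    if interactions is not None:
        data_io.write_interactions(interactions, outdir / "interactions.tsv")
    manifest = {"config": asdict(cfg), "seed": cfg.seed}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def validation_config(cfg: SyntheticConfig, seed_offset: int = 100003) -> SyntheticConfig:
    """Config for a paired validation cohort: same conditions, derived noise seed."""
    return replace(cfg, seed=(cfg.seed + seed_offset) % (2**31 - 1))
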