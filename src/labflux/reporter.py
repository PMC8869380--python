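"""DEG filtering and reporter-metabolite scoring.

Differential-expression integration follows the classical reporter-feature
scheme over the model's gene-metabolite graph. Each gene's p-value becomes
an inverse-normal score ``z_g = Phi^-1(1 - p_g)``; a metabolite with k
scored neighboring genes (genes in the GPRs of its reactions, currency
metabolites excluded) aggregates them as ``z_raw = sum(z_g) / sqrt(k)``.
Because metabolites with different k are not comparable, ``z_raw`` is
corrected against a sampled background: mean and standard deviation of the
same statistic over ``n_background`` random size-k gene draws (with
replacement) from the scored gene universe, seeded for reproducibility.
``p = 1 - Phi(z_corrected)`` then ranks metabolites whose neighborhoods show
coordinated expression change.

DEG filtering applies the conventional three-way rule: expressed
(FPKM >= 1), changed (|log2FC| >= 1.5), significant (FDR < 0.05).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import DEFAULT_CURRENCY, MetabolicModel, gene_metabolite_adjacency
from .errors import LabfluxError

__all__ = [
    "DEG_COLUMNS", "ReporterScore", "filter_degs", "read_deg_table",
    "reporter_scores", "summarize_routes",
    "FPKM_MIN", "ABS_LFC_MIN", "FDR_MAX",
]

# Conventional DEG thresholds.
FPKM_MIN = 1.0
ABS_LFC_MIN = 1.5
FDR_MAX = 0.05

DEG_COLUMNS = ("gene", "log2fc", "p", "fdr", "fpkm")

_P_CLAMP = 1e-15


@dataclass(frozen=True)
class ReporterScore:
    metabolite: str
    k: int
    z_raw: float
    z_corrected: float
    p: float


def _validate_degs(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DEG_COLUMNS if c not in records.columns]
    if missing:
        raise LabfluxError(f"DEG table lacks columns {missing}")
    for col in ("p", "fdr"):
        bad = records.index[(records[col] < 0) | (records[col] > 1)]
        if len(bad):
            raise LabfluxError(
                f"DEG table rows {list(bad[:5])}: {col} outside [0, 1]"
            )
    bad = records.index[records["fpkm"] < 0]
    if len(bad):
        raise LabfluxError(f"DEG table rows {list(bad[:5])}: negative fpkm")
    return records


def filter_degs(
    records: pd.DataFrame,
    fpkm_min: float = FPKM_MIN,
    abs_lfc_min: float = ABS_LFC_MIN,
    fdr_max: float = FDR_MAX,
) -> pd.DataFrame:
    """Keep rows with fpkm >= fpkm_min AND |log2fc| >= abs_lfc_min AND
    fdr < fdr_max (strict)."""
    _validate_degs(records)
    mask = (
        (records["fpkm"] >= fpkm_min)
        & (records["log2fc"].abs() >= abs_lfc_min)
        & (records["fdr"] < fdr_max)
    )
    return records[mask].copy()


def read_deg_table(path: str | Path) -> pd.DataFrame:
    """Read a DEG TSV.

    Accepts either the internal five-column layout (gene, log2fc, p, fdr,
    fpkm) or the two-condition dialect (gene, log2fc, p_value, fdr,
    fpkm_condition1, fpkm_condition2), in which case the expression filter
    uses the per-gene maximum of the two FPKM columns. Malformed rows raise
    with their line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise LabfluxError(f"{path}: cannot parse DEG table: {exc}") from exc
    if "p_value" in df.columns:
        df = df.rename(columns={"p_value": "p"})
    if "fpkm_condition1" in df.columns and "fpkm_condition2" in df.columns:
        df["fpkm"] = df[["fpkm_condition1", "fpkm_condition2"]].max(axis=1)
    missing = [c for c in DEG_COLUMNS if c not in df.columns]
    if missing:
        raise LabfluxError(f"{path}: DEG table lacks columns {missing}")
    for col in ("log2fc", "p", "fdr", "fpkm"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise LabfluxError(
                f"{path}: malformed value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = coerced
    return _validate_degs(df[list(DEG_COLUMNS)].copy())


def reporter_scores(
    model: MetabolicModel,
    gene_p: dict[str, float],
    direction: dict[str, float] | None = None,
    n_background: int = 10_000,
    seed: int | None = None,
    currency: frozenset[str] = DEFAULT_CURRENCY,
) -> list[ReporterScore]:
    """Score every metabolite with at least one scored neighboring gene.

    ``gene_p`` maps gene id to p-value; genes absent from the model are
    ignored. With ``direction`` (gene -> sign), gene scores are signed so
    coordinated up- and down-regulation pull a neighborhood in opposite
    directions; the default is non-directional. Results are sorted by
    descending corrected z, ties broken by metabolite id.
    """
    adjacency = gene_metabolite_adjacency(model, currency)
    scored = sorted(set(gene_p) & set(model.genes))
    if not scored:
        return []
    p = np.array([gene_p[g] for g in scored], dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "gene p-values at 0 or 1 clamped to the open unit interval",
            stacklevel=2,
        )
        p = np.clip(p, _P_CLAMP, 1 - _P_CLAMP)
    z = norm.isf(p)
    if direction is not None:
        signs = np.array([np.sign(direction.get(g, 1.0)) or 1.0 for g in scored])
        z = z * signs
    z_of = dict(zip(scored, z))
    scored_set = set(scored)

    neighborhoods = {
        mid: sorted(genes & scored_set)
        for mid, genes in adjacency.items()
        if genes & scored_set
    }
    rng = np.random.default_rng(seed)
    background: dict[int, tuple[float, float]] = {}
    for k in sorted({len(g) for g in neighborhoods.values()}):
        draws = rng.choice(z, size=(n_background, k), replace=True)
        sums = draws.sum(axis=1) / np.sqrt(k)
        background[k] = (float(sums.mean()), float(sums.std()))
    out = []
    for mid, genes in neighborhoods.items():
        k = len(genes)
        z_raw = sum(z_of[g] for g in genes) / np.sqrt(k)
        mu, sigma = background[k]
        z_corr = (z_raw - mu) / sigma if sigma > 1e-12 else 0.0
        out.append(ReporterScore(
            metabolite=mid, k=k, z_raw=float(z_raw),
            z_corrected=float(z_corr), p=float(norm.sf(z_corr)),
        ))
    out.sort(key=lambda s: (-s.z_corrected, s.metabolite))
    return out


def summarize_routes(
    scores: list[ReporterScore],
    model: MetabolicModel,
    top_n: int,
    currency: frozenset[str] = DEFAULT_CURRENCY,
) -> pd.DataFrame:
    """Top-scoring metabolites with the subsystems and genes around them.

    Subsystems come from the reactions touching each metabolite; the gene
    column lists the scored neighborhood that produced the score.
    """
    adjacency = gene_metabolite_adjacency(model, currency)
    subsystems_of: dict[str, set[str]] = {}
    for r in model.reactions:
        if not r.subsystem:
            continue
        for mid in r.stoichiometry:
            subsystems_of.setdefault(mid, set()).add(r.subsystem)
    rows = []
    for s in scores[: max(top_n, 0)]:
        rows.append({
            "metabolite": s.metabolite,
            "subsystems": "; ".join(sorted(subsystems_of.get(s.metabolite, ()))),
            "k": s.k,
            "z_corrected": s.z_corrected,
            "p": s.p,
            "genes": "; ".join(sorted(adjacency.get(s.metabolite, ()))),
        })
    return pd.DataFrame(
        rows, columns=["metabolite", "subsystems", "k", "z_corrected", "p", "genes"]
    )
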