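"""Off-target analysis: docking scores versus a clinical drug-risk ranking.

The study's headline question: do beta-blockers that bind gut hormone
receptors (class B GPCRs: GCGR, GIPR, GLP1R, VIPR1, PAC1R) more strongly
disturb glucose homeostasis less? Drugs carry an integer T2DM-risk rank from
clinical literature (1 = least disturbing; 0 = no clinical data, excluded
from statistics), and a score matrix holds docking scores per
(drug, receptor, site) with optional replicates, lower = stronger predicted
binding. A positive rank-score correlation then means the clinically safest
drugs dock best.

Two published rank assignments exist for the reference beta-blockers (they
differ in the nebivolol/carvedilol order); both ship as fixtures in
:mod:`gutdock.synthfix` and the choice is an explicit argument wherever it
matters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, InsufficientDataError

__all__ = [
    "ClinicalRankTable",
    "ScoreMatrix",
    "CorrelationResult",
    "rank_score_correlation",
    "combined_ranking",
    "compare_query",
    "RECEPTORS",
    "SITES",
]

#: The five class B GPCRs of the docking service.
RECEPTORS = ("GCGR", "GIPR", "GLP1R", "VIPR1", "PAC1R")
#: The two binding sites docked per receptor.
SITES = ("orthosteric", "allosteric")


@dataclass(frozen=True)
class ClinicalRankTable:
    """drug name -> T2DM-risk rank (1 = least disturbing, 0 = no data)."""

    entries: Mapping[str, int]
    name: str = ""

    def __post_init__(self):
        for drug, rank in self.entries.items():
            if int(rank) != rank or rank < 0:
                raise InputError(
                    f"rank for {drug!r} must be a non-negative integer, "
                    f"got {rank!r}"
                )

    def ranked_drugs(self) -> dict[str, int]:
        """Drugs with clinical data (rank > 0)."""
        return {d: r for d, r in self.entries.items() if r > 0}


@dataclass(frozen=True, eq=False)
class ScoreMatrix:
    """Long-form (drug, receptor, site, replicate) -> docking score table."""

    table: pd.DataFrame
    engine: str = "vina"

    _COLUMNS = ("drug", "receptor", "site", "replicate", "score")

    def __post_init__(self):
        df = pd.DataFrame(self.table)
        if "replicate" not in df.columns:
            df = df.assign(replicate=1)
        missing = set(self._COLUMNS) - set(df.columns)
        if missing:
            raise InputError(f"score table lacks columns {sorted(missing)}")
        df = df.loc[:, list(self._COLUMNS)].reset_index(drop=True)
        if not np.isfinite(df["score"].to_numpy(dtype=float)).all():
            raise InputError("docking scores must be finite")
        keys = df[["drug", "receptor", "site", "replicate"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise InputError(f"duplicated (drug, receptor, site, replicate) key: {dup}")
        object.__setattr__(self, "table", df)

    @classmethod
    def from_tsv(cls, path, engine: str = "vina") -> "ScoreMatrix":
        return cls(table=pd.read_csv(path, sep="\t"), engine=engine)

    @classmethod
    def from_dict(
        cls,
        scores: Mapping[tuple[str, str, str], float | Sequence[float]],
        engine: str = "vina",
    ) -> "ScoreMatrix":
        """Build from {(drug, receptor, site): score or replicate scores}."""
        rows = []
        for (drug, receptor, site), val in scores.items():
            vals = np.atleast_1d(np.asarray(val, dtype=float))
            for rep, s in enumerate(vals, 1):
                rows.append((drug, receptor, site, rep, float(s)))
        return cls(
            table=pd.DataFrame(rows, columns=list(cls._COLUMNS)),
            engine=engine,
        )

    def drugs(self) -> list[str]:
        return sorted(self.table["drug"].unique())

    def keys(self) -> list[tuple[str, str]]:
        """The (receptor, site) combinations present."""
        return sorted(
            set(map(tuple, self.table[["receptor", "site"]].values))
        )

    def mean_scores(self) -> pd.DataFrame:
        """Replicate means, indexed by (drug, receptor, site)."""
        return (
            self.table.groupby(["drug", "receptor", "site"])["score"]
            .mean()
            .to_frame()
        )

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class CorrelationResult:
    """Per-(receptor, site) rank-score correlation coefficients."""

    coefficients: Mapping[tuple[str, str], float]
    n_drugs: Mapping[tuple[str, str], int]
    method: str

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            (rec, site, self.coefficients[(rec, site)],
             self.n_drugs[(rec, site)], self.method)
            for rec, site in sorted(self.coefficients)
        ]
        return pd.DataFrame(
            rows,
            columns=["receptor", "site", "coefficient", "n_drugs", "method"],
        )


def _shared_rank_score(
    matrix: ScoreMatrix, ranks: ClinicalRankTable
) -> pd.DataFrame:
    ranked = ranks.ranked_drugs()
    means = matrix.mean_scores().reset_index()
    means = means[means["drug"].isin(ranked)]
    means["rank"] = means["drug"].map(ranked)
    return means


def rank_score_correlation(
    matrix: ScoreMatrix,
    ranks: ClinicalRankTable,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate clinical risk rank with docking score per (receptor, site).

    Drugs without clinical data (rank 0) are excluded; each (receptor, site)
    needs at least three shared ranked drugs. Pearson between integer rank
    and raw score is the default; Spearman is available for a purely ordinal
    reading.
    """
    if method not in ("pearson", "spearman"):
        raise InputError(f"unknown correlation method {method!r}")
    shared = _shared_rank_score(matrix, ranks)
    coeffs: dict[tuple[str, str], float] = {}
    ns: dict[tuple[str, str], int] = {}
    for (receptor, site), grp in shared.groupby(["receptor", "site"]):
        if len(grp) < 3:
            raise InsufficientDataError(
                f"{receptor}/{site}: only {len(grp)} drugs shared between "
                "the score matrix and the clinical ranking (need >= 3)"
            )
        if method == "pearson":
            coef = stats.pearsonr(grp["rank"], grp["score"]).statistic
        else:
            coef = stats.spearmanr(grp["rank"], grp["score"]).statistic
        coeffs[(receptor, site)] = float(coef)
        ns[(receptor, site)] = len(grp)
    if not coeffs:
        raise InsufficientDataError(
            "no (receptor, site) group shares >= 3 ranked drugs"
        )
    return CorrelationResult(coefficients=coeffs, n_drugs=ns, method=method)


def combined_ranking(
    matrix: ScoreMatrix,
    ranks: ClinicalRankTable,
    query: Mapping[tuple[str, str], float | Sequence[float]],
    query_name: str = "query",
) -> list[tuple[str, int]]:
    """Merge a query compound into the clinical ranking by mean docking score.

    Reference drugs keep their clinical ordering (ties by name). The query is
    inserted at the position given by how many references have a strictly
    better (lower) mean score; a tie resolves toward the reference. A query
    that outranks every reference takes the reserved rank 0 — the slot for a
    compound with no clinical data yet, like the newly discovered
    allosteric beta-blocker of the study's blind test — while the references
    keep ranks 1..n; otherwise ranks run 1..n+1 with the query in place.
    """
    ref_means = (
        matrix.mean_scores().reset_index().groupby("drug")["score"].mean()
    )
    required = set(matrix.keys())
    provided = set(query)
    if not required <= provided:
        raise InputError(
            f"query lacks scores for {sorted(required - provided)}"
        )
    q_mean = float(
        np.mean([np.mean(np.atleast_1d(np.asarray(query[k], dtype=float)))
                 for k in sorted(required)])
    )
    ranked = ranks.ranked_drugs()
    refs = sorted(
        (d for d in ref_means.index if d in ranked),
        key=lambda d: (ranked[d], d),
    )
    if not refs:
        raise InputError("no ranked reference drug present in the matrix")
    p = sum(1 for d in refs if ref_means[d] <= q_mean)
    if p == 0:
        out = [(query_name, 0)]
        out += [(d, i) for i, d in enumerate(refs, 1)]
        return out
    merged = refs[:p] + [query_name] + refs[p:]
    return [(d, i) for i, d in enumerate(merged, 1)]


def compare_query(
    reference: ScoreMatrix,
    query_scores: Mapping[tuple[str, str], float | Sequence[float]],
    ranks: Optional[ClinicalRankTable] = None,
    query_name: str = "query",
) -> pd.DataFrame:
    """Tabular comparison of a query against precomputed reference drugs.

    For every (receptor, site): reference drugs as (mean score, clinical
    rank) points and the query as an unranked marker, with dispersion = the
    sample standard deviation across replicates (zero for a single
    replicate). This is the plot-ready content of the service's comparison
    chart; no rendering backend is required.
    """
    if not query_scores:
        raise InputError("query has no scores")
    for key, val in query_scores.items():
        if len(np.atleast_1d(np.asarray(val, dtype=float))) == 0:
            raise InputError(f"query has an empty replicate list for {key}")
    stats_df = (
        reference.table.groupby(["drug", "receptor", "site"])["score"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1) if len(s) > 1 else 0.0,
             n_replicates="size")
        .reset_index()
    )
    rows = []
    for _, r in stats_df.iterrows():
        rank = ranks.entries.get(r["drug"]) if ranks is not None else None
        rows.append(
            (r["receptor"], r["site"], r["drug"], False, rank,
             r["mean"], r["sd"], int(r["n_replicates"]))
        )
    for (receptor, site), val in sorted(query_scores.items()):
        vals = np.atleast_1d(np.asarray(val, dtype=float))
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            (receptor, site, query_name, True, None,
             float(vals.mean()), sd, len(vals))
        )
    return pd.DataFrame(
        rows,
        columns=["receptor", "site", "drug", "is_query", "clinical_rank",
                 "mean_score", "score_sd", "n_replicates"],
    )
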