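"""RT-qPCR normalization: efficiency-corrected quantities, reference-gene
stability, and geometric-mean normalization.

Quantification-cycle (Cq) values are converted per gene into relative
quantities ``Q = (1 + E)^(Cq_min - Cq)`` with the gene's amplification
efficiency E (fraction form: E = 1 is perfect doubling).  Candidate
reference genes are ranked by the geNorm stability measure M — the mean,
over all other genes, of the standard deviation across samples of the
pairwise log2 expression ratio — and target genes are normalized against
the geometric mean of the chosen reference pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CqTable",
    "StabilityReport",
    "relative_quantity",
    "genorm_m",
    "select_references",
    "stability_report",
    "pairwise_variation",
    "normalize_targets",
    "summarize_replicates",
]


@dataclass(frozen=True)
class CqTable:
    """Samples x genes Cq matrix plus per-gene efficiencies.

    ``efficiencies`` are fractions in [0, 1]; use ``from_factor_form`` for
    amplification-factor inputs (e.g. 1.9 meaning E = 0.9).  Missing Cq
    (no amplification) may be NaN: it is excluded from the per-gene
    minimum and propagates as NaN quantity with a warning.
    """

    cq: pd.DataFrame
    efficiencies: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.cq.empty:
            raise ValueError("Cq table is empty")
        if (self.cq.dropna(how="all").shape[0] == 0
                or self.cq.isna().all().any()):
            raise ValueError("every gene needs at least one Cq value")
        if (self.cq.stack(future_stack=True).dropna() <= 0).any():
            raise ValueError("Cq values must be positive")
        missing = set(self.cq.columns) - set(self.efficiencies)
        if missing:
            raise ValueError(f"missing efficiencies for {sorted(missing)}")
        for gene in self.cq.columns:
            e = self.efficiencies[gene]
            if not 0.0 <= e <= 1.0:
                raise ValueError(
                    f"efficiency of {gene!r} is {e}; expected a fraction in "
                    "[0, 1] (use CqTable.from_factor_form for 1.x inputs)")

    @classmethod
    def from_factor_form(cls, cq: pd.DataFrame,
                         factors: Mapping[str, float]) -> "CqTable":
        """Accept efficiencies given as amplification factors (1..2)."""
        return cls(cq=cq, efficiencies={g: f - 1.0 for g, f in
                                        factors.items()})


def relative_quantity(table: CqTable) -> pd.DataFrame:
    """Efficiency-corrected relative quantities, max 1 per gene.

    ``Q_ij = (1 + E_j) ** (Cq_min_j - Cq_ij)`` with the per-gene minimum
    taken over non-missing samples.
    """
    q = pd.DataFrame(index=table.cq.index, columns=table.cq.columns,
                     dtype=float)
    for gene in table.cq.columns:
        cq = table.cq[gene].astype(float)
        base = 1.0 + table.efficiencies[gene]
        if cq.isna().any():
            warnings.warn(f"gene {gene!r}: {int(cq.isna().sum())} missing "
                          "Cq value(s) excluded and left as NaN",
                          stacklevel=2)
        q[gene] = base ** (cq.min(skipna=True) - cq)
    return q


@dataclass(frozen=True)
class StabilityReport:
    """geNorm output: per-gene M, stability ranking, chosen pair."""

    m_values: pd.Series
    ranked: tuple[str, ...]
    reference_pair: tuple[str, str]
    pairwise_variation: pd.Series = field(default_factory=lambda: pd.Series(
        dtype=float))


def genorm_m(q: pd.DataFrame) -> pd.Series:
    """geNorm expression-stability measure M per gene (lower = stabler).

    ``M_j = mean over k != j of SD across samples of log2(Q_j / Q_k)``.
    """
    if q.shape[1] < 2 or q.shape[0] < 2:
        raise ValueError("genorm_m needs >= 2 genes and >= 2 samples")
    if q.isna().any().any() or (q <= 0).any().any():
        raise ValueError("quantities must be positive and complete "
                         "(log-ratios undefined otherwise)")
    logq = np.log2(q.to_numpy(float))
    genes = list(q.columns)
    m = {}
    for j, gene in enumerate(genes):
        sds = [np.std(logq[:, j] - logq[:, k], ddof=1)
               for k in range(len(genes)) if k != j]
        m[gene] = float(np.mean(sds))
    return pd.Series(m, name="M")


def select_references(m_values: pd.Series, k: int = 2) -> tuple[str, ...]:
    """The k most stable genes (lowest M; ties broken lexicographically)."""
    if k > len(m_values):
        raise ValueError(f"k = {k} exceeds gene count {len(m_values)}")
    order = sorted(m_values.items(), key=lambda kv: (kv[1], kv[0]))
    return tuple(g for g, _ in order[:k])


def pairwise_variation(q: pd.DataFrame,
                       ranked: Sequence[str] | None = None) -> pd.Series:
    """geNorm V(n/n+1) series for growing reference sets.

    ``V_n = SD across samples of log2(NF_n / NF_{n+1})`` where ``NF_n`` is
    the geometric mean of the n most stable genes.  Reported for n = 2 ..
    genes-1; a diagnostic only (the reference count stays 2).
    """
    if ranked is None:
        ranked = select_references(genorm_m(q), k=q.shape[1])
    logq = np.log2(q[list(ranked)].to_numpy(float))
    out = {}
    for n in range(2, logq.shape[1]):
        nf_n = logq[:, :n].mean(axis=1)
        nf_n1 = logq[:, :n + 1].mean(axis=1)
        out[f"V{n}/{n + 1}"] = float(np.std(nf_n - nf_n1, ddof=1))
    return pd.Series(out, dtype=float)


def stability_report(q: pd.DataFrame, k: int = 2) -> StabilityReport:
    """Full geNorm pass: M values, ranking, chosen pair, V series."""
    m = genorm_m(q)
    ranked = select_references(m, k=len(m))
    pair = ranked[:k]
    if len(pair) != 2:
        raise ValueError("a reference *pair* (k = 2) is expected")
    return StabilityReport(m_values=m, ranked=ranked,
                           reference_pair=(pair[0], pair[1]),
                           pairwise_variation=pairwise_variation(q, ranked))


def normalize_targets(q: pd.DataFrame,
                      references: Sequence[str]) -> pd.DataFrame:
    """Normalize every gene against the geometric mean of the references.

    ``N_ij = Q_ij / geomean_ref(Q_i,ref)``; invariant to any per-sample
    global scaling of Q and to sample-independent rescaling of a
    reference gene.
    """
    refs = list(references)
    missing = set(refs) - set(q.columns)
    if missing:
        raise ValueError(f"reference genes not in table: {sorted(missing)}")
    ref_q = q[refs].to_numpy(float)
    if (ref_q <= 0).any() or np.isnan(ref_q).any():
        raise ValueError("reference quantities must be positive")
    nf = np.exp(np.log(ref_q).mean(axis=1))
    return q.div(nf, axis=0)


def summarize_replicates(normalized: pd.DataFrame,
                         groups: Sequence) -> pd.DataFrame:
    """Geometric mean ± SEM (on the log2 scale) over biological replicates.

    ``groups`` assigns each sample row to a sampling point; replicates are
    normalized individually first, then summarized.  Returns a tidy frame
    with one row per (group, gene).
    """
    frame = np.log2(normalized).assign(_group=list(groups))
    rows = []
    for group, grp in frame.groupby("_group"):
        vals = grp.drop(columns="_group")
        n = len(vals)
        mean = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else mean * np.nan
        for gene in vals.columns:
            rows.append({"group": group, "gene": gene, "n": n,
                         "geomean": float(2.0 ** mean[gene]),
                         "log2_mean": float(mean[gene]),
                         "log2_sem": float(sem[gene])})
    return pd.DataFrame(rows)
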