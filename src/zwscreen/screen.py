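"""Female-specific candidate screen over a pooled count matrix.

The screen applies three criteria to each contig: (i) reads come exclusively
from female pools, (ii) contig length strictly greater than a minimum
(default 500 bp), and (iii) a differential-expression posterior at (or
numerically indistinguishable from) 1.  The posterior is a two-model
comparison under a negative-binomial observation model with offsets
``library_size * contig_length``:

* M0: one shared expression rate theta for all pools;
* M1: separate rates theta_F, theta_M per sex.

Each model's score is its maximized log-likelihood minus a BIC penalty
``(k/2) * ln(n_pools)``; the posterior is the prior-weighted softmax of the
two scores, computed in log-space.  Dispersion is estimated per contig by
method of moments within each sex (no shrinkage across contigs).

`FemaleSpecificScreen` / `ScreenResults` wrap the per-contig machinery in a
fit-once, inspect-later interface; the module-level functions expose each
step individually.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

from .simulate import CountMatrix

__all__ = [
    "ScreenConfig",
    "DEResult",
    "AssemblyMetrics",
    "FemaleSpecificScreen",
    "ScreenResults",
    "normalize_counts",
    "estimate_dispersion",
    "de_posterior",
    "female_exclusive_filter",
    "select_candidates",
    "assembly_coverage",
    "compute_n50",
]


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the female-specific screen.

    ``min_length_bp`` = 501 makes the length criterion strictly > 500 bp.
    ``posterior_threshold`` operationalizes "differential-expression
    posterior of 1" as >= 1 - 1e-6.  ``max_male_reads_total`` = 0 demands
    strict female exclusivity; ``min_female_pools_present`` = 1 because a
    transcript assembled from a single pool's reads is still a candidate.
    """

    min_length_bp: int = 501
    posterior_threshold: float = 1.0 - 1e-6
    min_female_pools_present: int = 1
    max_male_reads_total: int = 0
    prior_de: float = 0.05
    exclusion_list: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not 0.0 < self.posterior_threshold <= 1.0:
            raise ValueError("posterior_threshold must be in (0, 1]")
        if not 0.0 < self.prior_de < 1.0:
            raise ValueError("prior_de must be in (0, 1)")
        if min(self.min_length_bp, self.min_female_pools_present) < 0:
            raise ValueError("thresholds must be non-negative")
        if self.max_male_reads_total < 0:
            raise ValueError("max_male_reads_total must be >= 0")
        object.__setattr__(self, "exclusion_list", frozenset(self.exclusion_list))


@dataclass(frozen=True)
class DEResult:
    """Fitted two-model comparison for one contig."""

    contig_id: str
    theta_null: float
    theta_f: float
    theta_m: float
    dispersion: float
    log_score_null: float
    log_score_de: float
    posterior_de: float
    converged: bool = True


@dataclass(frozen=True)
class AssemblyMetrics:
    """Contig-set summary statistics (N50, totals, per-contig coverage)."""

    kmer_size: int
    n_contigs: int
    total_length: int
    n50: int
    coverage_scores: tuple = ()

    @classmethod
    def from_lengths(cls, lengths, kmer_size: int = 0) -> "AssemblyMetrics":
        lengths = list(lengths)
        return cls(
            kmer_size=kmer_size,
            n_contigs=len(lengths),
            total_length=int(sum(lengths)),
            n50=compute_n50(lengths),
        )


def normalize_counts(matrix: CountMatrix) -> tuple[np.ndarray, float]:
    """Normalize counts over library size and gene length.

    ``rate[i, j] = counts[i, j] / (library_size[j] * contig_length[i]) * scale``
    with ``scale = median(library_size) * median(contig_length)`` so values
    stay on a readable reads-like scale.  Returns ``(rates, scale)``.
    """
    if np.any(matrix.contig_length <= 0):
        bad = matrix.contig_ids[int(np.argmax(matrix.contig_length <= 0))]
        raise ValueError(f"non-positive contig length for {bad}")
    if np.any(matrix.library_size <= 0):
        bad = matrix.pool_ids[int(np.argmax(matrix.library_size <= 0))]
        raise ValueError(f"non-positive library size for pool {bad}")
    scale = float(np.median(matrix.library_size) * np.median(matrix.contig_length))
    rates = (
        matrix.counts
        / (matrix.library_size[None, :] * matrix.contig_length[:, None])
        * scale
    )
    return rates, scale


def estimate_dispersion(
    row_counts,
    library_sizes,
    contig_length: float,
    pool_sex=None,
) -> tuple[float, bool]:
    """Method-of-moments NB dispersion for one contig row.

    Counts are rescaled to a common offset within each group (a sex, or the
    whole row when ``pool_sex`` is None); each group with >= 2 pools and a
    positive mean contributes ``(s^2 - m) / m^2`` (sample variance s^2 with
    ddof=1, mean m), and group estimates are pooled with df weights then
    floored at 0.  Returns ``(phi_hat, all_zero_flag)``.
    """
    y = np.asarray(row_counts, dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 pools to estimate dispersion")
    offsets = lib * float(contig_length)
    if np.all(y == 0):
        return 0.0, True
    if pool_sex is None:
        groups = [np.ones(y.size, dtype=bool)]
    else:
        sexes = np.asarray(pool_sex)
        groups = [sexes == s for s in ("F", "M")]
    num = den = 0.0
    for g in groups:
        if g.sum() < 2:
            continue
        x = y[g] / offsets[g] * offsets[g].mean()
        m = x.mean()
        if m <= 0:
            continue
        s2 = x.var(ddof=1)
        df = g.sum() - 1
        num += df * (s2 - m) / m**2
        den += df
    phi = num / den if den > 0 else 0.0
    return max(0.0, float(phi)), False


def _nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    """NB log-likelihood with variance mu + phi*mu^2; Poisson at phi == 0.

    Pools with mu == 0 contribute 0 when y == 0 and -inf otherwise.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    out = 0.0
    zero = mu == 0
    if zero.any():
        if np.any(y[zero] > 0):
            return -np.inf
        y, mu = y[~zero], mu[~zero]
        if y.size == 0:
            return 0.0
    if phi <= 1e-12:
        out += float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    else:
        r = 1.0 / phi
        out += float(
            np.sum(
                gammaln(y + r)
                - gammaln(r)
                - gammaln(y + 1)
                + r * np.log(r / (r + mu))
                + y * np.log(mu / (r + mu))
            )
        )
    return out


def _fit_rate(y: np.ndarray, offsets: np.ndarray, phi: float) -> tuple[float, float, bool]:
    """Maximize the NB likelihood over a single rate theta (mu = theta*offset).

    Returns ``(theta_hat, loglik, converged)``.  All-zero counts give the
    exact boundary solution theta = 0 with log-likelihood 0.
    """
    y = np.asarray(y, dtype=float)
    total = y.sum()
    if total == 0:
        return 0.0, 0.0, True
    theta0 = total / offsets.sum()  # exact Poisson MLE; NB optimum is nearby

    def nll(log_t: float) -> float:
        return -_nb_loglik(y, np.exp(log_t) * offsets, phi)

    res = minimize_scalar(
        nll,
        bounds=(np.log(theta0) - 4.0, np.log(theta0) + 4.0),
        method="bounded",
        options={"xatol": 1e-8},
    )
    theta = float(np.exp(res.x))
    ll = -float(res.fun)
    ll0 = _nb_loglik(y, theta0 * offsets, phi)
    if ll0 > ll:  # guard: never worse than the Poisson-MLE start
        theta, ll = theta0, ll0
    return theta, ll, bool(res.success)


def de_posterior(
    row_counts,
    library_sizes,
    contig_length: float,
    pool_sex,
    config: ScreenConfig | None = None,
    dispersion: float | None = None,
    contig_id: str = "",
) -> DEResult:
    """Posterior probability that a contig is differentially expressed by sex.

    Fits the shared-rate model M0 and the per-sex model M1 by maximum
    likelihood with offsets ``library_size * contig_length``, penalizes each
    maximized log-likelihood by ``(k/2) ln(n_pools)`` (BIC), and combines the
    scores with the prior ``config.prior_de`` in log-space.
    """
    config = config or ScreenConfig()
    y = np.asarray(row_counts, dtype=float)
    sexes = np.asarray(pool_sex)
    f_mask = sexes == "F"
    m_mask = sexes == "M"
    if not (f_mask.any() and m_mask.any()):
        raise ValueError("both sexes must be represented among pools")
    offsets = np.asarray(library_sizes, dtype=float) * float(contig_length)
    if dispersion is None:
        dispersion, _ = estimate_dispersion(
            y, library_sizes, contig_length, pool_sex=sexes
        )

    n = y.size
    theta0, ll0, ok0 = _fit_rate(y, offsets, dispersion)
    theta_f, ll_f, ok_f = _fit_rate(y[f_mask], offsets[f_mask], dispersion)
    theta_m, ll_m, ok_m = _fit_rate(y[m_mask], offsets[m_mask], dispersion)
    score_null = ll0 - 0.5 * 1 * np.log(n)
    score_de = (ll_f + ll_m) - 0.5 * 2 * np.log(n)

    log_prior = np.log([1.0 - config.prior_de, config.prior_de])
    log_w = log_prior + np.array([score_null, score_de])
    posterior = float(np.exp(log_w[1] - logsumexp(log_w)))
    return DEResult(
        contig_id=contig_id,
        theta_null=theta0,
        theta_f=theta_f,
        theta_m=theta_m,
        dispersion=float(dispersion),
        log_score_null=float(score_null),
        log_score_de=float(score_de),
        posterior_de=posterior,
        converged=ok0 and ok_f and ok_m,
    )


def female_exclusive_filter(row_counts, pool_sex, config: ScreenConfig | None = None) -> bool:
    """True iff a row's reads are (configurably) exclusive to female pools.

    Total male-pool reads must not exceed ``max_male_reads_total`` (default
    0) and at least ``min_female_pools_present`` female pools must hold >= 1
    read.
    """
    config = config or ScreenConfig()
    y = np.asarray(row_counts)
    sexes = np.asarray(pool_sex)
    male_total = int(y[sexes == "M"].sum())
    female_present = int((y[sexes == "F"] >= 1).sum())
    return (
        male_total <= config.max_male_reads_total
        and female_present >= config.min_female_pools_present
    )


class FemaleSpecificScreen:
    """Model object: the three-criterion screen over one count matrix.

    Parameters
    ----------
    matrix : CountMatrix
        Per-contig, per-pool counts with pool sex labels and offsets.
    config : ScreenConfig, optional
        Screen thresholds; defaults reproduce the standard settings.

    Examples
    --------
    >>> screen = FemaleSpecificScreen(matrix)
    >>> results = screen.fit()
    >>> results.candidates["contig_id"].tolist()
    """

    def __init__(self, matrix: CountMatrix, config: ScreenConfig | None = None):
        self.matrix = matrix
        self.config = config or ScreenConfig()
        unknown = set(self.config.exclusion_list) - set(matrix.contig_ids)
        if unknown:
            warnings.warn(
                f"exclusion list names {len(unknown)} unknown contig id(s): "
                f"{sorted(unknown)[:5]}",
                stacklevel=2,
            )

    @classmethod
    def from_tsv(cls, counts_path, pools_path, config: ScreenConfig | None = None):
        return cls(CountMatrix.from_tsv(counts_path, pools_path), config)

    def fit(self) -> "ScreenResults":
        """Evaluate every contig against all criteria; returns ScreenResults."""
        m, cfg = self.matrix, self.config
        sexes = np.asarray(m.pool_sex)
        rows = []
        de_results = []
        for i, cid in enumerate(m.contig_ids):
            y = m.counts[i]
            length = int(m.contig_length[i])
            de = de_posterior(
                y, m.library_size, length, sexes, cfg, contig_id=cid
            )
            de_results.append(de)
            exclusive = female_exclusive_filter(y, sexes, cfg)
            rows.append(
                {
                    "contig_id": cid,
                    "length": length,
                    "posterior_de": de.posterior_de,
                    "exclusive": exclusive,
                    "length_ok": length >= cfg.min_length_bp,
                    "posterior_ok": de.posterior_de >= cfg.posterior_threshold,
                    "excluded_as_contaminant": cid in cfg.exclusion_list,
                }
            )
        report = pd.DataFrame(rows)
        report["final_candidate"] = (
            report["exclusive"]
            & report["length_ok"]
            & report["posterior_ok"]
            & ~report["excluded_as_contaminant"]
        )
        report = report.sort_values(
            ["posterior_de", "contig_id"], ascending=[False, True]
        ).reset_index(drop=True)
        return ScreenResults(self, report, de_results)


@dataclass
class ScreenResults:
    """Fit results of :class:`FemaleSpecificScreen`.

    ``report`` is the full per-contig table with criterion flags (one row per
    contig, ordered by descending posterior then contig id);
    ``candidates`` restricts it to final candidates.
    """

    model: FemaleSpecificScreen
    report: pd.DataFrame
    de_results: list

    @property
    def candidates(self) -> pd.DataFrame:
        return self.report[self.report["final_candidate"]].reset_index(drop=True)

    def summary(self) -> str:
        r = self.report
        cfg = self.model.config
        rows = [
            ("contigs screened", len(r)),
            ("female-exclusive", int(r["exclusive"].sum())),
            (f"length > {cfg.min_length_bp - 1} bp", int(r["length_ok"].sum())),
            (
                f"posterior >= {cfg.posterior_threshold:.6f}",
                int(r["posterior_ok"].sum()),
            ),
            ("excluded as contaminant", int(r["excluded_as_contaminant"].sum())),
            ("final candidates", int(r["final_candidate"].sum())),
        ]
        lines = ["Female-specific candidate screen", "=" * 40]
        lines += [f"{label:<30s}{value:>10d}" for label, value in rows]
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        out = self.report.copy()
        for col in ("exclusive", "length_ok", "posterior_ok",
                    "excluded_as_contaminant", "final_candidate"):
            out[col] = out[col].astype(int)
        out["posterior_de"] = out["posterior_de"].map(lambda p: f"{p:.6f}")
        out.to_csv(path, sep="\t", index=False)


def select_candidates(
    matrix: CountMatrix, config: ScreenConfig | None = None
) -> ScreenResults:
    """Run the full screen; convenience wrapper over FemaleSpecificScreen."""
    return FemaleSpecificScreen(matrix, config).fit()


def assembly_coverage(
    gene_length_bp: float,
    avg_utr_length_bp: float,
    contig_length_bp: int,
    n_count: int = 0,
) -> float:
    """Reference-gene coverage of a contig, excluding ambiguous bases.

    ``(gene_length + average UTR length) / (contig_length - N count)``.
    """
    denom = contig_length_bp - n_count
    if denom <= 0 or n_count < 0:
        raise ValueError("contig length excluding N's must be positive")
    return (gene_length_bp + avg_utr_length_bp) / denom


def compute_n50(lengths) -> int:
    """N50: largest L with contigs >= L totalling at least half the assembly."""
    lengths = sorted(int(x) for x in lengths)
    if not lengths:
        raise ValueError("empty length list")
    if any(x <= 0 for x in lengths):
        raise ValueError("contig lengths must be positive")
    half = sum(lengths) / 2.0
    acc = 0
    for x in reversed(lengths):
        acc += x
        if acc >= half:
            return x
    return lengths[0]
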