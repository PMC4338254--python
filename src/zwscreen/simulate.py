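"""Synthetic ZW gonad-transcriptome generator.

Emulates the statistical structure of a pooled-gonad RNA-seq screen for
W-linked transcripts in a female-heterogametic (ZW/ZZ) fish: a transcript
universe with W-linked, sex-biased, autosomal and contaminant classes; a
pooled count matrix with negative-binomial noise; ortholog pairs for
species-diagnostic primer design; and genotyping cohorts for marker
validation.  Every operation is seeded and bit-reproducible, with
per-transcript child RNG streams so output is invariant to evaluation order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "TranscriptModel",
    "PoolDesign",
    "CountMatrix",
    "CohortRecord",
    "CLASS_LABELS",
    "DEFAULT_CLASS_PROPORTIONS",
    "simulate_transcriptome",
    "simulate_count_matrix",
    "simulate_ortholog_pair",
    "simulate_validation_cohort",
    "replica_cohort",
    "transcripts_to_fasta",
    "truth_table",
]

CLASS_LABELS = (
    "autosomal",
    "z_linked",
    "w_linked",
    "female_biased",
    "male_biased",
    "contaminant",
)

#: Default class mix: mostly autosomal background, a small W-linked target
#: class, modest sex-biased fractions, and a sliver of contaminants.
DEFAULT_CLASS_PROPORTIONS: dict[str, float] = {
    "autosomal": 0.90,
    "w_linked": 0.02,
    "female_biased": 0.03,
    "male_biased": 0.03,
    "contaminant": 0.02,
}

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class ConfigurationError(ValueError):
    """Raised when simulator parameters are inconsistent or out of range."""


@dataclass(frozen=True)
class TranscriptModel:
    """One simulated transcript with its true class and expression law.

    ``base_rate`` is the expected number of reads per base pair per unit of
    library size; the expected count of a pool is
    ``base_rate * sex_multiplier * length_bp * library_size``.
    ``fold_change`` is the favored-sex/other-sex expression ratio for the
    biased classes and is 1 for unbiased classes.
    """

    transcript_id: str
    length_bp: int
    n_count: int
    class_label: str
    base_rate: float
    fold_change: float
    sequence: str
    #: for contaminants only: indices of pools where the transcript is present
    expressed_pools: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ConfigurationError(f"unknown class label {self.class_label!r}")
        if self.length_bp != len(self.sequence):
            raise ConfigurationError(
                f"{self.transcript_id}: length_bp {self.length_bp} != sequence length"
            )
        if self.base_rate <= 0:
            raise ConfigurationError(f"{self.transcript_id}: base_rate must be > 0")
        if self.class_label in ("autosomal", "contaminant") and self.fold_change != 1.0:
            raise ConfigurationError(
                f"{self.transcript_id}: fold_change must be 1 for {self.class_label}"
            )


@dataclass(frozen=True)
class PoolDesign:
    """The pooled sequencing design: pools per sex, fish per pool, depth.

    Defaults reproduce a 6 + 6 design with two fish per pool.  Library sizes
    are drawn log-normal around ``target_library_size`` with coefficient of
    variation ``library_size_cv``; gene-wise negative-binomial dispersions are
    drawn log-normal.
    """

    n_female_pools: int = 6
    n_male_pools: int = 6
    fish_per_pool: int = 2
    target_library_size: float = 1e6
    library_size_cv: float = 0.2
    dispersion_log_mean: float = float(np.log(0.1))
    dispersion_log_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_female_pools, self.n_male_pools, self.fish_per_pool) < 1:
            raise ConfigurationError("pool counts and fish per pool must be >= 1")
        if self.target_library_size <= 0:
            raise ConfigurationError("target_library_size must be > 0")
        if self.library_size_cv < 0:
            raise ConfigurationError("library_size_cv must be >= 0")

    @property
    def n_pools(self) -> int:
        return self.n_female_pools + self.n_male_pools

    @property
    def pool_ids(self) -> list[str]:
        return [f"F{i + 1}" for i in range(self.n_female_pools)] + [
            f"M{i + 1}" for i in range(self.n_male_pools)
        ]

    @property
    def pool_sex(self) -> list[str]:
        return ["F"] * self.n_female_pools + ["M"] * self.n_male_pools


@dataclass
class CountMatrix:
    """Per-contig, per-pool read counts with pool metadata.

    Rows are contigs, columns are pools.  ``library_size`` and
    ``contig_length`` carry the normalization offsets used throughout the
    screen.
    """

    contig_ids: list[str]
    pool_ids: list[str]
    pool_sex: list[str]
    library_size: np.ndarray
    contig_length: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.library_size = np.asarray(self.library_size, dtype=float)
        self.contig_length = np.asarray(self.contig_length, dtype=int)
        self.counts = np.asarray(self.counts)
        n_contigs, n_pools = self.counts.shape
        if n_contigs != len(self.contig_ids) or n_pools != len(self.pool_ids):
            raise ConfigurationError("count matrix dimensions do not match id lists")
        if len(self.pool_sex) != n_pools or len(self.library_size) != n_pools:
            raise ConfigurationError("pool metadata length does not match pool ids")
        if len(self.contig_length) != n_contigs:
            raise ConfigurationError("contig_length does not match contig ids")
        if np.any(self.library_size <= 0):
            raise ConfigurationError("library sizes must be positive")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ConfigurationError("counts must be non-negative integers")

    @property
    def n_contigs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_pools(self) -> int:
        return self.counts.shape[1]

    def sex_mask(self, sex: str) -> np.ndarray:
        return np.array([s == sex for s in self.pool_sex], dtype=bool)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=self.pool_ids)
        df.insert(0, "contig_id", self.contig_ids)
        df.insert(1, "length", self.contig_length)
        return df

    def pool_metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pool_id": self.pool_ids,
                "sex": self.pool_sex,
                "library_size": self.library_size,
            }
        )

    def to_tsv(self, counts_path, pools_path) -> None:
        self.to_frame().to_csv(counts_path, sep="\t", index=False)
        self.pool_metadata().to_csv(pools_path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, counts_path, pools_path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t")
        pools = pd.read_csv(pools_path, sep="\t")
        pool_ids = list(pools["pool_id"].astype(str))
        return cls(
            contig_ids=list(df["contig_id"].astype(str)),
            pool_ids=pool_ids,
            pool_sex=list(pools["sex"].astype(str)),
            library_size=pools["library_size"].to_numpy(dtype=float),
            contig_length=df["length"].to_numpy(dtype=int),
            counts=df[pool_ids].to_numpy(dtype=np.int64),
        )


@dataclass(frozen=True)
class CohortRecord:
    """One genotyped individual in a marker-validation cohort."""

    individual_id: str
    population: str
    phenotypic_sex: str
    genotype: str
    band_observed: bool


def _child_rng(seed: int, index: int) -> np.random.Generator:
    # per-item stream: independent of how many siblings are drawn before it
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _largest_remainder(proportions: dict[str, float], n: int) -> dict[str, int]:
    labels = sorted(proportions)
    exact = {k: proportions[k] * n for k in labels}
    counts = {k: int(np.floor(exact[k])) for k in labels}
    short = n - sum(counts.values())
    by_remainder = sorted(labels, key=lambda k: (-(exact[k] - counts[k]), k))
    for k in by_remainder[:short]:
        counts[k] += 1
    return counts


def simulate_transcriptome(
    n_transcripts: int,
    class_proportions: dict[str, float] | None = None,
    length_range: tuple[int, int] = (600, 2400),
    seed: int = 0,
    *,
    fold_change: float = 4.0,
    base_rate_range: tuple[float, float] = (1e-7, 5e-7),
    n_fraction: float = 0.0,
    design: PoolDesign | None = None,
) -> list[TranscriptModel]:
    """Draw a transcript universe with known class labels.

    Class counts follow ``class_proportions`` after largest-remainder
    rounding.  Sequences are i.i.d. uniform over ACGT; a fraction
    ``n_fraction`` of bases is replaced by N (default 0).  ``base_rate`` is
    log-uniform over ``base_rate_range``; at the defaults the expected
    female-pool count of a W-linked transcript is at least
    ``1e-7 * 600 * 1e6 = 60`` reads at the nominal library size, keeping the
    target class comfortably above the ~20 reads/pool regime where the
    screen's sensitivity is expected to be complete.  Contaminant transcripts are assigned a
    random subset of pools (``expressed_pools``) where they are present
    regardless of sex, which is how chance female-only contaminants arise.

    Parameters
    ----------
    design
        Pool design used only to size contaminant pool subsets
        (defaults to the standard 6 + 6 design).
    """
    if n_transcripts <= 0:
        raise ConfigurationError("n_transcripts must be a positive integer")
    props = dict(class_proportions or DEFAULT_CLASS_PROPORTIONS)
    unknown = set(props) - set(CLASS_LABELS)
    if unknown:
        raise ConfigurationError(f"unknown class labels {sorted(unknown)}")
    if any(v < 0 for v in props.values()):
        raise ConfigurationError("class proportions must be non-negative")
    if abs(sum(props.values()) - 1.0) > 1e-9:
        raise ConfigurationError("class proportions must sum to 1")
    lo, hi = length_range
    if lo < 100 or hi < lo:
        raise ConfigurationError("length_range must satisfy 100 <= min <= max")
    if not 0.0 <= n_fraction < 1.0:
        raise ConfigurationError("n_fraction must be in [0, 1)")

    design = design or PoolDesign()
    counts = _largest_remainder(props, n_transcripts)
    labels: list[str] = []
    for k in sorted(counts):
        labels.extend([k] * counts[k])

    rate_lo, rate_hi = base_rate_range
    transcripts: list[TranscriptModel] = []
    for i, label in enumerate(labels):
        rng = _child_rng(seed, i)
        length = int(rng.integers(lo, hi + 1))
        seq_arr = _BASES[rng.integers(0, 4, size=length)]
        n_count = 0
        if n_fraction > 0:
            n_mask = rng.random(length) < n_fraction
            n_count = int(n_mask.sum())
            seq_arr = seq_arr.copy()
            seq_arr[n_mask] = b"N"
        base_rate = float(np.exp(rng.uniform(np.log(rate_lo), np.log(rate_hi))))
        fc = fold_change if label in ("female_biased", "male_biased") else 1.0
        expressed = None
        if label == "contaminant":
            present = rng.random(design.n_pools) < 0.5
            if not present.any():
                present[int(rng.integers(design.n_pools))] = True
            expressed = tuple(int(j) for j in np.flatnonzero(present))
        transcripts.append(
            TranscriptModel(
                transcript_id=f"contig{i:05d}",
                length_bp=length,
                n_count=n_count,
                class_label=label,
                base_rate=base_rate,
                fold_change=fc,
                sequence=seq_arr.tobytes().decode(),
                expressed_pools=expressed,
            )
        )
    return transcripts


def _sex_multipliers(t: TranscriptModel, design: PoolDesign) -> np.ndarray:
    """Per-pool expression multiplier implementing each class's law."""
    female = np.array([s == "F" for s in design.pool_sex])
    mult = np.ones(design.n_pools)
    if t.class_label == "w_linked":
        mult[~female] = 0.0
    elif t.class_label == "female_biased":
        mult[female] = t.fold_change
    elif t.class_label == "male_biased":
        mult[~female] = t.fold_change
    elif t.class_label == "contaminant":
        mult[:] = 0.0
        mult[list(t.expressed_pools or ())] = 1.0
    return mult


def simulate_count_matrix(
    transcripts: list[TranscriptModel], design: PoolDesign
) -> CountMatrix:
    """Draw a pooled count matrix under the negative-binomial noise model.

    Counts are NB with mean ``base_rate * multiplier * length * library_size``
    and gene-wise dispersion phi (variance = mu + phi * mu**2) drawn
    log-normal; phi -> 0 degrades to Poisson.  W-linked rows are structurally
    zero in male pools because their male multiplier is zero.
    """
    if not transcripts:
        raise ConfigurationError("at least one transcript required")
    if design.n_female_pools < 1 or design.n_male_pools < 1:
        raise ConfigurationError("need at least one pool per sex")

    lib_rng = _child_rng(design.seed, 2**20)  # offset from per-transcript streams
    if design.library_size_cv > 0:
        sigma = float(np.sqrt(np.log1p(design.library_size_cv**2)))
        mu = np.log(design.target_library_size) - sigma**2 / 2
        library_size = np.exp(lib_rng.normal(mu, sigma, size=design.n_pools))
    else:
        library_size = np.full(design.n_pools, design.target_library_size)

    counts = np.zeros((len(transcripts), design.n_pools), dtype=np.int64)
    for i, t in enumerate(transcripts):
        rng = _child_rng(design.seed, i)
        phi = float(
            np.exp(rng.normal(design.dispersion_log_mean, design.dispersion_log_sd))
        )
        mean = t.base_rate * _sex_multipliers(t, design) * t.length_bp * library_size
        counts[i] = _nb_draw(rng, mean, phi)
    return CountMatrix(
        contig_ids=[t.transcript_id for t in transcripts],
        pool_ids=design.pool_ids,
        pool_sex=design.pool_sex,
        library_size=library_size,
        contig_length=np.array([t.length_bp for t in transcripts]),
        counts=counts,
    )


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) sample; exact zeros where mean == 0, Poisson when phi == 0."""
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if not pos.any():
        return out
    if phi <= 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / phi
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_ortholog_pair(
    template: str, substitution_rate: float, seed: int = 0
) -> tuple[str, str, list[int]]:
    """Mutate ``template`` at a known set of sites to make an ortholog pair.

    Returns ``(sequence_a, sequence_b, positions)`` where ``sequence_a`` is
    the template, ``sequence_b`` carries ``round(rate * len)`` substitutions
    placed uniformly without replacement, and ``positions`` are the 0-based
    mutated sites (sorted).  Substituted bases always differ from the
    original.
    """
    if not 0.0 <= substitution_rate <= 0.25:
        raise ConfigurationError("substitution_rate must be in [0, 0.25]")
    if not template or any(c not in "ACGT" for c in template):
        raise ConfigurationError("template must be non-empty over ACGT")
    rng = np.random.default_rng(seed)
    n_sub = int(round(substitution_rate * len(template)))
    positions = sorted(int(p) for p in rng.choice(len(template), n_sub, replace=False))
    seq_b = list(template)
    for p in positions:
        alternatives = [b for b in "ACGT" if b != template[p]]
        seq_b[p] = alternatives[int(rng.integers(3))]
    return template, "".join(seq_b), positions


def simulate_validation_cohort(
    n_per_group: dict[tuple[str, str], int],
    sex_reversal_rate: float = 0.0,
    seed: int = 0,
) -> list[CohortRecord]:
    """Generate a genotyping cohort with optional sex-reversed individuals.

    Genotype is set from phenotypic sex (F -> ZW, M -> ZZ) and flipped with
    probability ``sex_reversal_rate``; the female-specific band is observed
    iff the genotype is ZW (no assay dropout).
    """
    if not 0.0 <= sex_reversal_rate <= 1.0:
        raise ConfigurationError("sex_reversal_rate must be in [0, 1]")
    if any(n < 0 for n in n_per_group.values()):
        raise ConfigurationError("group counts must be >= 0")
    rng = np.random.default_rng(seed)
    records: list[CohortRecord] = []
    idx = 0
    for (population, sex) in sorted(n_per_group):
        if sex not in ("F", "M"):
            raise ConfigurationError(f"phenotypic sex must be F or M, got {sex!r}")
        for _ in range(n_per_group[(population, sex)]):
            genotype = "ZW" if sex == "F" else "ZZ"
            if rng.random() < sex_reversal_rate:
                genotype = "ZZ" if genotype == "ZW" else "ZW"
            records.append(
                CohortRecord(
                    individual_id=f"ind{idx:05d}",
                    population=population,
                    phenotypic_sex=sex,
                    genotype=genotype,
                    band_observed=(genotype == "ZW"),
                )
            )
            idx += 1
    return records


def replica_cohort() -> list[CohortRecord]:
    """Deterministic 115-individual replica of the validation study design.

    115 individuals: 25 females and 19 males from Mexico, 28 females and 42
    males from New Zealand, all concordant, plus one phenotypic female with a
    ZZ genotype (no band) whose population of origin is deliberately left
    unassigned.  Synthetic stand-in for the genotyping table, which is not
    published per individual.
    """
    groups = {
        ("Mexico", "F"): 25,
        ("Mexico", "M"): 19,
        ("NewZealand", "F"): 28,
        ("NewZealand", "M"): 42,
    }
    records = simulate_validation_cohort(groups, sex_reversal_rate=0.0, seed=0)
    records.append(
        CohortRecord(
            individual_id="ind_discordant",
            population="unassigned",
            phenotypic_sex="F",
            genotype="ZZ",
            band_observed=False,
        )
    )
    return records


def transcripts_to_fasta(transcripts: list[TranscriptModel], path=None) -> str:
    """Write transcripts as FASTA; returns the text (and writes if path given)."""
    buf = io.StringIO()
    for t in transcripts:
        buf.write(f">{t.transcript_id} class={t.class_label} length={t.length_bp}\n")
        seq = t.sequence
        for i in range(0, len(seq), 70):
            buf.write(seq[i : i + 70] + "\n")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def truth_table(transcripts: list[TranscriptModel]) -> pd.DataFrame:
    """Truth table of ids, classes and expression parameters as a DataFrame."""
    return pd.DataFrame(
        {
            "transcript_id": [t.transcript_id for t in transcripts],
            "class": [t.class_label for t in transcripts],
            "length": [t.length_bp for t in transcripts],
            "n_count": [t.n_count for t in transcripts],
            "base_rate": [t.base_rate for t in transcripts],
            "fold_change": [t.fold_change for t in transcripts],
        }
    )


def cohort_to_frame(records: list[CohortRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "population": [r.population for r in records],
            "phenotypic_sex": [r.phenotypic_sex for r in records],
            "genotype": [r.genotype for r in records],
            "band_observed": [int(r.band_observed) for r in records],
        }
    )
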