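"""Synthetic small-RNA sequencing data with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a two-line x two-condition x k-replicate pool design, element mean
abundances drawn from a heavy-tailed (log-normal) law so that RPM values are
strongly skewed to low values, negative-binomial replicate noise with a
configurable coefficient of variation, a small set of elements given
line-specific multiplicative injury effects (the "spike-ins" that a correct
analysis should recover), and optionally one compositionally distorted
outlier pool. Raw reads can be emitted as FASTQ (insert + 3' adapter, with
optional non-templated additions and adapter corruption) to exercise the
editing stage.

All randomness flows from ``SyntheticConfig.seed``; the same configuration
always yields bit-identical output.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import PoolDesign
from . import io as _io

# Illumina TruSeq small-RNA 3' adapter.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

RNA_BASES = np.array(list("ACGU"))

# Tri-modal read-length law: most mass at miRNA-like 22 nt, side modes at
# 17-18 nt and 33 nt, a thin uniform tail over the full retained range.
LENGTH_MODES: tuple[tuple[int, float], ...] = (
    (17, 0.10),
    (18, 0.10),
    (22, 0.50),
    (33, 0.20),
)
LENGTH_TAIL_RANGE = (16, 41)
LENGTH_TAIL_WEIGHT = 0.10


@dataclass(frozen=True)
class SpikeIn:
    """A line-specific injury effect on one element.

    ``fold`` multiplies the element's mean RPM in the SNL condition of
    ``line`` only; values < 1 encode down-regulation.
    """

    element: str
    line: str = "HA"
    fold: float = 2.0


@dataclass(frozen=True)
class OutlierPool:
    """Compositional distortion of a single pool.

    A random ``fraction`` of elements in that pool have their expected
    counts multiplied by i.i.d. log-uniform factors in
    ``[1/inflation, inflation]``.
    """

    pool: str
    inflation: float = 3.0
    fraction: float = 0.3


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic count generator.

    Parameters
    ----------
    n_elements:
        Number of distinct small-RNA elements.
    abundance_meanlog, abundance_sdlog:
        Location/scale of the log-normal law for element mean abundance.
        Abundances are rescaled so baseline mean RPMs sum to 10^6, which
        makes ``abundance_meanlog`` a shape-neutral offset; it is kept for
        transparency of the law.
    cv:
        Target within-group coefficient of variation of replicate counts
        (negative-binomial overdispersion). Sampling never goes below the
        Poisson floor, so very low-abundance elements are noisier than
        ``cv``.
    noise:
        ``"nb"`` (default), ``"poisson"`` (dispersion -> 0 limit) or
        ``"none"`` (replicates equal expected counts exactly).
    spike_ins:
        Line-specific injury effects; the ground-truth differential set.
    outlier:
        Optional outlier-pool perturbation.
    total_reads_per_pool:
        Expected library size per pool.
    seed:
        Seed for every random draw.
    """

    n_elements: int = 300
    abundance_meanlog: float = 6.0
    abundance_sdlog: float = 2.0
    cv: float = 0.2
    design: PoolDesign = field(default_factory=PoolDesign)
    spike_ins: tuple[SpikeIn, ...] = ()
    outlier: OutlierPool | None = None
    adapter: str = DEFAULT_ADAPTER
    total_reads_per_pool: int = 2_000_000
    noise: str = "nb"
    seed: int = 0

    def validate(self) -> None:
        if self.n_elements < 1:
            raise ValueError("n_elements must be positive")
        if self.total_reads_per_pool <= 0:
            raise ValueError("total_reads_per_pool must be positive")
        if self.design.replicates < 2:
            raise ValueError("need at least 2 replicate pools per group")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.noise not in ("nb", "poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")
        pools = self.design.pools
        for spike in self.spike_ins:
            if spike.fold <= 0:
                raise ValueError("spike-in folds must be strictly positive")
            if spike.line not in self.design.lines:
                raise ValueError(f"spike-in line {spike.line!r} not in design")
        if self.outlier is not None:
            if self.outlier.pool not in pools:
                raise ValueError(f"outlier pool {self.outlier.pool!r} not in design")
            if self.outlier.inflation <= 1:
                raise ValueError("outlier inflation must exceed 1")
            if not 0 < self.outlier.fraction <= 1:
                raise ValueError("outlier fraction must be in (0, 1]")


@dataclass
class GroundTruth:
    """True generative state serialized alongside synthetic data."""

    group_mean_rpm: pd.DataFrame
    spike_ins: tuple[SpikeIn, ...]
    outlier_pool: str | None

    @property
    def diff_reg_elements(self) -> list[str]:
        return sorted({s.element for s in self.spike_ins})

    def to_json(self, path: str | Path) -> None:
        payload = {
            "group_mean_rpm": {
                col: self.group_mean_rpm[col].round(6).to_dict()
                for col in self.group_mean_rpm.columns
            },
            "spike_ins": [asdict(s) for s in self.spike_ins],
            "outlier_pool": self.outlier_pool,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            group_mean_rpm=pd.DataFrame(payload["group_mean_rpm"]),
            spike_ins=tuple(SpikeIn(**s) for s in payload["spike_ins"]),
            outlier_pool=payload["outlier_pool"],
        )


def element_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"el{i:0{width}d}" for i in range(1, n + 1)]


def _draw_base_rpm(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Log-normal mean abundances rescaled to an RPM budget of 10^6."""
    raw = rng.lognormal(config.abundance_meanlog, config.abundance_sdlog, config.n_elements)
    return raw / raw.sum() * 1e6


def generate_counts(config: SyntheticConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a counts matrix (elements x pools) plus its ground truth.

    Returns
    -------
    counts:
        Integer counts, one column per pool of ``config.design``; column
        sums are approximately ``config.total_reads_per_pool``.
    truth:
        Per-group true mean RPM (spike-ins applied, outlier distortion not
        included), the spike-in list and the outlier pool identity.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ids = element_ids(config.n_elements)
    id_pos = {e: i for i, e in enumerate(ids)}

    base_rpm = _draw_base_rpm(config, rng)
    groups = config.design.groups
    group_rpm = pd.DataFrame(
        {f"{line}_{cond}": base_rpm.copy() for (line, cond) in groups},
        index=ids,
    )
    for spike in config.spike_ins:
        if spike.element not in id_pos:
            raise ValueError(f"spike-in element {spike.element!r} not in element set")
        group_rpm.loc[spike.element, f"{spike.line}_SNL"] *= spike.fold

    scale = config.total_reads_per_pool / 1e6
    counts = {}
    for (line, cond), pools in groups.items():
        mean_counts = group_rpm[f"{line}_{cond}"].to_numpy() * scale
        for pool in pools:
            mu = mean_counts
            if config.outlier is not None and pool == config.outlier.pool:
                mu = mu * _outlier_factors(config, rng)
            counts[pool] = _draw_counts(mu, config, rng)
    matrix = pd.DataFrame(counts, index=ids, columns=config.design.pools)
    matrix.index.name = "element"
    truth = GroundTruth(
        group_mean_rpm=group_rpm,
        spike_ins=tuple(config.spike_ins),
        outlier_pool=None if config.outlier is None else config.outlier.pool,
    )
    return matrix, truth


def _outlier_factors(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_elements
    spec = config.outlier
    assert spec is not None
    factors = np.ones(n)
    hit = rng.random(n) < spec.fraction
    log_bound = np.log(spec.inflation)
    factors[hit] = np.exp(rng.uniform(-log_bound, log_bound, hit.sum()))
    return factors


def _draw_counts(mu: np.ndarray, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if config.noise == "none":
        return np.rint(mu).astype(np.int64)
    if config.noise == "poisson" or config.cv == 0:
        return rng.poisson(mu).astype(np.int64)
    var = (config.cv * mu) ** 2
    out = np.empty(mu.shape, dtype=np.int64)
    # below the Poisson floor the NB parameterization degenerates
    poisson_like = var <= mu * (1 + 1e-9)
    out[poisson_like] = rng.poisson(mu[poisson_like])
    over = ~poisson_like
    if over.any():
        m = mu[over]
        r = m**2 / (var[over] - m)
        p = r / (r + m)
        out[over] = rng.negative_binomial(r, p)
    return out


def make_study_config(
    seed: int,
    n_elements: int = 300,
    cv: float = 0.2,
    spike_fraction: float = 0.05,
    fold_range: tuple[float, float] = (1.5, 3.0),
    min_spike_rpm: float = 1000.0,
    outlier: OutlierPool | None = None,
    **kwargs,
) -> SyntheticConfig:
    """Build a config whose spike-ins sit on well-measured elements.

    Spiked elements are chosen among elements whose baseline mean RPM is at
    least ``min_spike_rpm`` (falling back to the most abundant elements if
    fewer qualify); each gets a fold drawn from ``fold_range``, inverted
    with probability 1/2 to mix up- and down-regulation, on a random line.
    The element abundances seen here are identical to the ones
    ``generate_counts`` will draw, because both use the first draws of the
    generator seeded with ``seed``.
    """
    base = SyntheticConfig(n_elements=n_elements, cv=cv, seed=seed, **kwargs)
    abundance = _draw_base_rpm(base, np.random.default_rng(seed))
    ids = np.array(element_ids(n_elements))
    eligible = np.flatnonzero(abundance >= min_spike_rpm)
    n_spikes = max(1, round(spike_fraction * n_elements))
    pick_rng = np.random.default_rng([seed, 91])
    if len(eligible) < n_spikes:
        eligible = np.argsort(abundance)[-max(n_spikes, 1):]
    chosen = pick_rng.choice(eligible, size=n_spikes, replace=False)
    spikes = []
    for idx in sorted(chosen):
        fold = pick_rng.uniform(*fold_range)
        if pick_rng.random() < 0.5:
            fold = 1.0 / fold
        line = base.design.lines[pick_rng.integers(len(base.design.lines))]
        spikes.append(SpikeIn(element=str(ids[idx]), line=line, fold=float(fold)))
    return SyntheticConfig(
        n_elements=n_elements,
        cv=cv,
        seed=seed,
        spike_ins=tuple(spikes),
        outlier=outlier,
        **kwargs,
    )


def generate_sequences(
    n_elements: int,
    seed: int = 0,
    length_modes: Sequence[tuple[int, float]] = LENGTH_MODES,
) -> pd.Series:
    """Random unique RNA sequences with a tri-modal length distribution."""
    rng = np.random.default_rng([seed, 17])
    lo, hi = LENGTH_TAIL_RANGE
    lengths = list(range(lo, hi + 1))
    probs = np.full(len(lengths), LENGTH_TAIL_WEIGHT / len(lengths))
    for length, weight in length_modes:
        probs[lengths.index(length)] += weight
    probs /= probs.sum()
    seen: set[str] = set()
    seqs: list[str] = []
    while len(seqs) < n_elements:
        length = int(rng.choice(lengths, p=probs))
        seq = "".join(rng.choice(RNA_BASES, size=length))
        if seq not in seen:
            seen.add(seq)
            seqs.append(seq)
    return pd.Series(seqs, index=element_ids(n_elements), name="sequence")


def emit_fastq(
    matrix: pd.DataFrame,
    sequences: Mapping[str, str] | pd.Series,
    adapter: str,
    outdir: str | Path,
    nta_fraction: float = 0.0,
    adapter_truncation_rate: float = 0.0,
    truncated_adapter_len: int = 9,
    adapter_mismatch_rate: float = 0.0,
    seed: int = 0,
) -> dict[str, Path]:
    """Write per-pool FASTQ files realizing a counts matrix.

    Each read is ``insert + adapter`` in DNA alphabet with constant Phred
    quality. A ``nta_fraction`` of reads carries a 1-2 nt non-templated
    A/U addition between insert and adapter; ``adapter_truncation_rate``
    reads get only ``truncated_adapter_len`` nt of adapter (below the 10-nt
    detection minimum by default, making them uneditable downstream);
    ``adapter_mismatch_rate`` reads carry one substitution inside the
    written adapter.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([seed, 23])
    seqs = dict(sequences)
    for element in matrix.index:
        seq = seqs.get(element)
        if seq is None:
            raise ValueError(f"no sequence for element {element!r}")
        if not 16 <= len(seq) <= 41:
            raise ValueError(f"sequence for {element!r} outside 16-41 nt")
    adapter_dna = adapter.upper().replace("U", "T")
    paths: dict[str, Path] = {}
    dna_bases = "ACGT"
    for pool in matrix.columns:
        reads: list[tuple[str, str]] = []
        for element, count in matrix[pool].items():
            count = int(count)
            if count <= 0:
                continue
            insert = seqs[element].upper().replace("U", "T")
            for i in range(count):
                body = insert
                if nta_fraction and rng.random() < nta_fraction:
                    body += "".join(rng.choice(list("AT"), size=rng.integers(1, 3)))
                ad = adapter_dna
                if adapter_truncation_rate and rng.random() < adapter_truncation_rate:
                    ad = ad[:truncated_adapter_len]
                elif adapter_mismatch_rate and rng.random() < adapter_mismatch_rate:
                    pos = int(rng.integers(len(ad)))
                    alt = dna_bases.replace(ad[pos], "")
                    ad = ad[:pos] + alt[int(rng.integers(len(alt)))] + ad[pos + 1:]
                reads.append((f"{element}_{pool}_{i}", body + ad))
        path = outdir / f"{pool}.fastq"
        _io.write_fastq(path, reads)
        paths[pool] = path
    return paths
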