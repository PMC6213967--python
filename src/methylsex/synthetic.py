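"""Synthetic methylation cohorts with sex-specific distributional structure.

The generator emulates exactly the features the estimator exploits, per
karyotype:

* **XX** — chrX beta-values carry a heavy intermediate (~0.5) component from
  X-inactivation; chrY probes have no target, so their beta-values are
  diffuse noise and their detection p-values are large.
* **XY** — chrX and chrY beta-values are genome-typical bimodal (peaks near 0
  and 1, little intermediate mass); all probes detect confidently.
* **XXY** (Klinefelter-like) — female-like chrX (one X inactivated) with a
  male-like, confidently detected chrY.
* **X0** (Turner-like) — male-like chrX (the single X is active and not
  inactivated) with an absent, female-like chrY.

Beta-values are drawn from three-component Beta mixtures
(low / intermediate / high methylation); detection p-values are drawn
log-normally on the log10 scale — present chromosomes centre near 1e-8,
absent ones near 0.3.  Autosomal probes are generated bimodal with no sex
signal, only to make inputs realistic and exercise manifest filtering.
Everything is reproducible from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .profiles import MethylationMatrix, ProbeAnnotation

KARYOTYPES = ("XX", "XY", "XXY", "X0")
#: the call the estimator is expected to produce per karyotype
EXPECTED_CALL = {"XX": "F", "XY": "M", "XXY": "N", "X0": "N"}
#: the sex recorded on the sample sheet (Klinefelter individuals are males,
#: Turner individuals females)
SEX_LABEL = {"XX": "F", "XY": "M", "XXY": "M", "X0": "F"}


@dataclass(frozen=True)
class BetaMixture:
    """Three-component Beta mixture: (low, intermediate, high) methylation.

    ``weights`` must sum to 1; each component is Beta(a, b) with a, b > 0.
    """

    weights: tuple[float, float, float]
    low: tuple[float, float] = (2.0, 25.0)
    mid: tuple[float, float] = (10.0, 10.0)
    high: tuple[float, float] = (25.0, 2.0)

    def __post_init__(self) -> None:
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValidationError("mixture weights must sum to 1")
        if min(self.weights) < 0:
            raise ValidationError("mixture weights must be >= 0")
        for a, b in (self.low, self.mid, self.high):
            if a <= 0 or b <= 0:
                raise ValidationError("Beta shapes must be > 0")


def bimodal_mixture(intermediate_weight: float = 0.10) -> BetaMixture:
    """Genome-typical bimodal shape: mass near 0 and 1, a small middle."""
    w = float(intermediate_weight)
    return BetaMixture(weights=((1 - w) / 2, w, (1 - w) / 2))


def xci_mixture(intermediate_weight: float = 0.5) -> BetaMixture:
    """Female-chrX shape: a substantial intermediate component from XCI."""
    w = float(intermediate_weight)
    return BetaMixture(weights=((1 - w) / 2, w, (1 - w) / 2))


@dataclass
class SimulationConfig:
    """Cohort layout, effect sizes and noise for the generator.

    ``xci_intermediate_weight`` is the mixture weight of the intermediate
    methylation component on a two-X chromosome (the XCI signature, default
    0.5); ``bimodal_intermediate_weight`` is the residual middle mass of the
    genome-typical shape (default 0.10).  ``detected_logp`` /
    ``undetected_logp`` are (mean, sd) of log10 detection p-values for
    present / absent chromosomes; noise is a bounded uniform perturbation of
    beta-values, clamped to [0, 1].
    """

    n_xx: int = 50
    n_xy: int = 50
    n_xxy: int = 0
    n_x0: int = 0
    n_probes_chrx: int = 1000
    n_probes_chry: int = 400
    n_probes_autosome: int = 2000
    xci_intermediate_weight: float = 0.5
    bimodal_intermediate_weight: float = 0.10
    absent_beta_shapes: tuple[float, float] = (1.5, 1.5)
    detected_logp: tuple[float, float] = (-8.0, 1.5)
    undetected_logp: tuple[float, float] = (-0.5, 0.8)
    noise_scale: float = 0.01
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_xx", "n_xy", "n_xxy", "n_x0"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.n_samples == 0:
            raise ValidationError("cohort has zero samples")
        if self.n_probes_chrx < 1 or self.n_probes_chry < 1:
            raise ValidationError("need at least one probe on each sex chromosome")
        if not 0 <= self.missing_rate < 1:
            raise ValidationError("missing_rate must be in [0, 1)")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")

    @property
    def n_samples(self) -> int:
        return self.n_xx + self.n_xy + self.n_xxy + self.n_x0

    def counts(self) -> dict[str, int]:
        return {"XX": self.n_xx, "XY": self.n_xy, "XXY": self.n_xxy, "X0": self.n_x0}

    def beta_mixture(self, karyotype: str, chrom: str) -> BetaMixture | None:
        """Mixture for a present chromosome; None when the chromosome is
        absent from the karyotype (chrY in XX and X0)."""
        if chrom == "chrY" and karyotype in ("XX", "X0"):
            return None
        if chrom == "chrX" and karyotype in ("XX", "XXY"):
            return xci_mixture(self.xci_intermediate_weight)
        return bimodal_mixture(self.bimodal_intermediate_weight)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("absent_beta_shapes", "detected_logp", "undetected_logp"):
            if k in d and isinstance(d[k], (list, tuple)):
                d[k] = tuple(float(x) for x in d[k])
        return cls(**d)


@dataclass
class SimulatedCohort:
    """A generated cohort: matrices, manifest and per-sample ground truth.

    ``truth`` is indexed by sample ID with columns ``karyotype``,
    ``expected_call`` (F/M/N) and ``sex_label`` (the label a sample sheet
    would carry).
    """

    matrix: MethylationMatrix
    annot: ProbeAnnotation
    truth: pd.DataFrame
    config: SimulationConfig


def _draw_mixture(rng: np.random.Generator, mix: BetaMixture, size: tuple[int, int]) -> np.ndarray:
    comp = rng.choice(3, size=size, p=mix.weights)
    a = np.array([mix.low[0], mix.mid[0], mix.high[0]])[comp]
    b = np.array([mix.low[1], mix.mid[1], mix.high[1]])[comp]
    return rng.beta(a, b)


def simulate_cohort(config: SimulationConfig) -> SimulatedCohort:
    """Generate a cohort under ``config``; bit-reproducible from its seed."""
    rng = np.random.default_rng(config.seed)
    probe_ids = (
        [f"cgX{i:05d}" for i in range(config.n_probes_chrx)]
        + [f"cgY{i:05d}" for i in range(config.n_probes_chry)]
        + [f"cgA{i:05d}" for i in range(config.n_probes_autosome)]
    )
    chrom_of = (
        ["chrX"] * config.n_probes_chrx
        + ["chrY"] * config.n_probes_chry
        + ["autosome"] * config.n_probes_autosome
    )
    annot = ProbeAnnotation(
        chromosome=pd.Series(chrom_of, index=pd.Index(probe_ids, name="probe_id"))
    )

    n_by_chrom = {
        "chrX": config.n_probes_chrx,
        "chrY": config.n_probes_chry,
        "autosome": config.n_probes_autosome,
    }
    sample_ids: list[str] = []
    truth_rows: list[dict] = []
    beta_cols: list[np.ndarray] = []
    detp_cols: list[np.ndarray] = []
    for kt in KARYOTYPES:
        n = config.counts()[kt]
        if n == 0:
            continue
        for i in range(n):
            sample_ids.append(f"{kt}_{i + 1:04d}")
            truth_rows.append(
                {"karyotype": kt, "expected_call": EXPECTED_CALL[kt], "sex_label": SEX_LABEL[kt]}
            )
        beta_blocks = []
        detp_blocks = []
        for chrom in ("chrX", "chrY", "autosome"):
            shape = (n_by_chrom[chrom], n)
            mix = config.beta_mixture(kt, chrom)
            if mix is None:
                beta = rng.beta(*config.absent_beta_shapes, size=shape)
                loc, scale = config.undetected_logp
            else:
                beta = _draw_mixture(rng, mix, shape)
                loc, scale = config.detected_logp
            if config.noise_scale > 0:
                beta = beta + rng.uniform(-config.noise_scale, config.noise_scale, size=shape)
            beta = np.clip(beta, 0.0, 1.0)
            detp = np.clip(10.0 ** rng.normal(loc, scale, size=shape), 0.0, 1.0)
            beta_blocks.append(beta)
            detp_blocks.append(detp)
        beta_cols.append(np.vstack(beta_blocks))
        detp_cols.append(np.vstack(detp_blocks))

    beta = np.hstack(beta_cols)
    detp = np.hstack(detp_cols)
    if config.missing_rate > 0:
        beta[rng.random(beta.shape) < config.missing_rate] = np.nan
        detp[rng.random(detp.shape) < config.missing_rate] = np.nan

    index = pd.Index(probe_ids, name="probe_id")
    columns = pd.Index(sample_ids, name="sample_id")
    matrix = MethylationMatrix(
        beta=pd.DataFrame(beta, index=index, columns=columns),
        detp=pd.DataFrame(detp, index=index, columns=columns),
    )
    truth = pd.DataFrame(truth_rows, index=columns.copy())
    return SimulatedCohort(matrix=matrix, annot=annot, truth=truth, config=config)


def flip_labels(
    labels: pd.Series, k: int, seed: int = 0, eligible: pd.Series | None = None
) -> tuple[pd.Series, pd.Index]:
    """Swap F<->M on exactly ``k`` eligible samples; returns (labels, index).

    ``eligible`` defaults to samples whose label is F or M.  Used to fabricate
    mislabelled sample sheets for testing discordance detection.
    """
    labels = pd.Series(labels).astype(str).str.upper()
    if eligible is None:
        eligible = labels.isin(["F", "M"])
    eligible = pd.Series(eligible).reindex(labels.index, fill_value=False)
    pool = labels.index[eligible & labels.isin(["F", "M"])]
    if k < 0 or k > len(pool):
        raise ValidationError(f"cannot flip {k} labels: only {len(pool)} eligible samples")
    rng = np.random.default_rng(seed)
    chosen = pd.Index(sorted(rng.choice(np.asarray(pool, dtype=object), size=k, replace=False)))
    flipped = labels.copy()
    flipped.loc[chosen] = flipped.loc[chosen].map({"F": "M", "M": "F"})
    return flipped, chosen
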