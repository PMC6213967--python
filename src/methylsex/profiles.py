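"""Distribution profiles of methylation arrays on the sex chromosomes.

Each Infinium-style array sample carries, per probe, a beta-value (methylation
level in [0, 1]) and a detection p-value (confidence that the probe signal
exceeds background).  Because of X-chromosome inactivation, female samples
show substantial intermediate (~0.5) methylation on chrX, while males show the
genome-typical bimodal shape; chrY probes in female samples yield no credible
signal, pushing their detection p-values high.  This module turns raw
probe-by-sample matrices into the binned per-chromosome proportion vectors
("profiles") that downstream clustering consumes, computes beta-values from
raw signals when only those are available, and applies the sample-level
quality-control rule based on chrX detection p-values.

Binning convention: intervals are left-open/right-closed, ``edges[i] < v <=
edges[i+1]``, except the first bin which also contains its lower edge so that
``v == 0`` is not lost.  Every proportion vector over usable probes sums to 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import ValidationError

log = logging.getLogger(__name__)

#: chromosome groups a profile is computed for
CHROMOSOMES = ("chrX", "chrY")
#: metrics profiled per chromosome
METRICS = ("beta", "detp")

_CHROM_TOKENS = {
    "x": "chrX",
    "chrx": "chrX",
    "y": "chrY",
    "chry": "chrY",
}


def normalise_chromosome(token: str) -> str:
    """Map a manifest chromosome token to {autosome, chrX, chrY}.

    "X"/"chrX" and "Y"/"chrY" (any case) map to the sex chromosomes;
    every other token is treated as autosomal.
    """
    return _CHROM_TOKENS.get(str(token).strip().lower(), "autosome")


def _check_edges(edges: Iterable[float], what: str) -> tuple[float, ...]:
    e = tuple(float(x) for x in edges)
    if len(e) < 2:
        raise ValidationError(f"{what}: need at least 2 edges, got {len(e)}")
    if e[0] != 0.0 or e[-1] != 1.0:
        raise ValidationError(f"{what}: edges must start at 0 and end at 1, got {e[0]}..{e[-1]}")
    if any(b <= a for a, b in zip(e, e[1:])):
        raise ValidationError(f"{what}: edges must be strictly increasing")
    return e


@dataclass(frozen=True)
class BinScheme:
    """Ordered interval edges for beta-values and detection p-values.

    The number of bins per metric is ``len(edges) - 1``.  The default scheme
    uses 10 beta bins of width 0.1 and 3 detection-p bins with interior edges
    at 1e-5 and 1e-2.
    """

    beta_edges: tuple[float, ...]
    detp_edges: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "beta_edges", _check_edges(self.beta_edges, "beta_edges"))
        object.__setattr__(self, "detp_edges", _check_edges(self.detp_edges, "detp_edges"))

    @classmethod
    def default(
        cls,
        n_beta_bins: int = 10,
        detp_interior: Iterable[float] = (1e-5, 1e-2),
    ) -> "BinScheme":
        """Equal-width beta bins plus detection-p edges at 0, interior..., 1."""
        if n_beta_bins < 1:
            raise ValidationError("n_beta_bins must be >= 1")
        beta = tuple(i / n_beta_bins for i in range(n_beta_bins + 1))
        detp = (0.0, *sorted(float(x) for x in detp_interior), 1.0)
        return cls(beta_edges=beta, detp_edges=detp)

    @classmethod
    def fine(cls) -> "BinScheme":
        """The fine scheme used by reference panels: 100 beta bins of width
        0.01 and 18 detection-p bins with decade edges from 1e-17 to 1."""
        beta = tuple(i / 100 for i in range(101))
        detp = (0.0, *(10.0 ** k for k in range(-17, 0)), 1.0)
        return cls(beta_edges=beta, detp_edges=detp)

    def edges(self, metric: str) -> tuple[float, ...]:
        if metric == "beta":
            return self.beta_edges
        if metric == "detp":
            return self.detp_edges
        raise ValidationError(f"unknown metric {metric!r}")

    @property
    def n_beta_bins(self) -> int:
        return len(self.beta_edges) - 1

    @property
    def n_detp_bins(self) -> int:
        return len(self.detp_edges) - 1


@dataclass
class ProbeAnnotation:
    """Probe -> chromosome mapping (autosome / chrX / chrY).

    ``chromosome`` is a Series indexed by probe ID.  Probe IDs must be unique;
    downstream estimation additionally requires at least one chrX and one chrY
    probe shared with the data matrix.
    """

    chromosome: pd.Series

    def __post_init__(self) -> None:
        s = pd.Series(self.chromosome)
        if s.index.has_duplicates:
            dup = s.index[s.index.duplicated()][0]
            raise ValidationError(f"duplicate probe ID in manifest: {dup!r}")
        bad = set(s.unique()) - {"autosome", "chrX", "chrY"}
        if bad:
            raise ValidationError(f"unnormalised chromosome values: {sorted(bad)}")
        self.chromosome = s

    @classmethod
    def from_tokens(cls, tokens: Mapping[str, str] | pd.Series) -> "ProbeAnnotation":
        s = pd.Series(tokens)
        return cls(chromosome=s.map(normalise_chromosome))

    @property
    def probe_ids(self) -> pd.Index:
        return self.chromosome.index

    def probes(self, chrom: str) -> pd.Index:
        return self.chromosome.index[self.chromosome == chrom]

    def counts(self) -> dict[str, int]:
        return self.chromosome.value_counts().to_dict()


@dataclass
class MethylationMatrix:
    """Beta-values and detection p-values for probes x samples.

    Both matrices (when present) share the same probe index and sample
    columns, with values in [0, 1] or NaN for missing.  One of the two may be
    None for operations that only need the other (e.g. QC needs only detp).
    """

    beta: pd.DataFrame | None
    detp: pd.DataFrame | None

    def __post_init__(self) -> None:
        if self.beta is None and self.detp is None:
            raise ValidationError("need at least one of beta / detp")
        for name in ("beta", "detp"):
            df = getattr(self, name)
            if df is None:
                continue
            if df.index.has_duplicates:
                raise ValidationError(f"{name}: duplicate probe IDs")
            if df.columns.has_duplicates:
                raise ValidationError(f"{name}: duplicate sample IDs")
            vals = df.to_numpy(dtype=float)
            with np.errstate(invalid="ignore"):
                if np.nanmin(vals, initial=0.0) < 0 or np.nanmax(vals, initial=1.0) > 1:
                    raise ValidationError(f"{name}: values outside [0, 1]")
        if self.beta is not None and self.detp is not None:
            if not self.beta.index.equals(self.detp.index) or not self.beta.columns.equals(
                self.detp.columns
            ):
                raise ValidationError("beta and detp must share probe and sample indices")

    @classmethod
    def from_parts(
        cls, beta: pd.DataFrame | None, detp: pd.DataFrame | None
    ) -> "MethylationMatrix":
        """Align beta and detp on their shared probes and samples."""
        if beta is not None and detp is not None:
            probes = beta.index.intersection(detp.index)
            samples = beta.columns.intersection(detp.columns)
            if len(probes) == 0 or len(samples) == 0:
                raise ValidationError("beta and detp share no probes or no samples")
            n_drop = max(len(beta.index), len(detp.index)) - len(probes)
            if n_drop:
                log.info("dropping %d probes absent from one of beta/detp", n_drop)
            beta = beta.loc[probes, samples]
            detp = detp.loc[probes, samples]
        return cls(beta=beta, detp=detp)

    @property
    def probe_ids(self) -> pd.Index:
        df = self.beta if self.beta is not None else self.detp
        return df.index

    @property
    def sample_ids(self) -> pd.Index:
        df = self.beta if self.beta is not None else self.detp
        return df.columns


def compute_beta(methylated, unmethylated, offset: float = 100.0):
    """Beta-value from raw signals: M / (M + U + offset), clamped to [0, 1].

    The additive ``offset`` (default 100, the conventional stabilising
    constant) guards against near-zero total intensity.  An all-zero
    denominator yields NaN with a warning.  Accepts scalars or arrays.
    """
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if offset < 0:
        raise ValidationError("offset must be >= 0")
    if np.nanmin(m, initial=0.0) < 0 or np.nanmin(u, initial=0.0) < 0:
        raise ValidationError("signals must be non-negative")
    denom = m + u + offset
    zero = denom == 0
    if np.any(zero):
        warnings.warn("zero total signal: beta set to missing", RuntimeWarning, stacklevel=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(zero, np.nan, m / np.where(zero, 1.0, denom))
    beta = np.clip(beta, 0.0, 1.0)
    if np.isscalar(methylated) and np.isscalar(unmethylated):
        return float(beta)
    return beta


def _bin_indices(values: np.ndarray, edges: np.ndarray) -> np.ndarray:
    # right-closed bins; the clip keeps v == edges[0] in bin 0
    idx = np.searchsorted(edges, values, side="left") - 1
    return np.clip(idx, 0, len(edges) - 2)


def bin_proportions(values, edges) -> np.ndarray:
    """Proportion of values per interval under the right-closed convention.

    Bin ``i`` counts values with ``edges[i] < v <= edges[i+1]``; bin 0 also
    includes ``v == edges[0]``.  Missing values are dropped first; an input
    with no usable values is an error (it signals a chromosome with no
    measured probes, from which no profile can be formed).
    """
    e = np.asarray(_check_edges(edges, "edges"))
    vals = np.asarray(values, dtype=float).ravel()
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError("no usable (non-missing) values to bin")
    if vals.min() < e[0] or vals.max() > e[-1]:
        raise ValidationError("values outside the edge range")
    counts = np.bincount(_bin_indices(vals, e), minlength=len(e) - 1)
    return counts / counts.sum()


@dataclass
class ProfileTable:
    """Binned proportion vectors per (sample, chromosome, metric).

    ``tables[(chrom, metric)]`` is a samples x bins DataFrame whose columns
    are the bin upper edges; each row sums to 1.  ``n_probes[(chrom, metric)]``
    records how many non-missing probes went into each row.
    """

    scheme: BinScheme
    tables: dict[tuple[str, str], pd.DataFrame]
    n_probes: dict[tuple[str, str], pd.Series] = field(default_factory=dict)

    @property
    def sample_ids(self) -> pd.Index:
        return next(iter(self.tables.values())).index

    def features(self, axis: str) -> pd.DataFrame:
        """Feature block for one clustering axis: the chromosome's beta bins
        concatenated with its detection-p bins (string column names)."""
        chrom = {"X": "chrX", "Y": "chrY"}.get(axis)
        if chrom is None:
            raise ValidationError(f"axis must be 'X' or 'Y', got {axis!r}")
        parts = []
        for metric in METRICS:
            df = self.tables[(chrom, metric)]
            df = df.copy()
            df.columns = [f"{metric}<={c:g}" for c in df.columns]
            parts.append(df)
        return pd.concat(parts, axis=1)

    def subset(self, sample_ids) -> "ProfileTable":
        ids = pd.Index(sample_ids)
        missing = ids.difference(self.sample_ids)
        if len(missing):
            raise ValidationError(f"unknown sample IDs: {list(missing)[:5]}")
        return ProfileTable(
            scheme=self.scheme,
            tables={k: v.loc[ids] for k, v in self.tables.items()},
            n_probes={k: v.loc[ids] for k, v in self.n_probes.items()},
        )


def build_profiles(
    matrix: MethylationMatrix, annot: ProbeAnnotation, scheme: BinScheme | None = None
) -> ProfileTable:
    """Compute per-sample chrX/chrY profiles for beta and detection p-values.

    Probes are matched between matrix and manifest by intersection (dropped
    counts are logged — this is what lets EPIC data run against a 450k-style
    reference).  Missing values are excluded per metric before binning; a
    sample x chromosome x metric with zero usable probes raises.
    """
    scheme = scheme or BinScheme.default()
    common = matrix.probe_ids.intersection(annot.probe_ids)
    n_dropped = len(matrix.probe_ids) - len(common)
    if n_dropped:
        log.info("probe intersection dropped %d of %d matrix probes", n_dropped, len(matrix.probe_ids))
    if len(matrix.sample_ids) == 0:
        raise ValidationError("matrix contains no samples")

    chrom_of = annot.chromosome.loc[common]
    tables: dict[tuple[str, str], pd.DataFrame] = {}
    n_probes: dict[tuple[str, str], pd.Series] = {}
    samples = matrix.sample_ids
    for chrom in CHROMOSOMES:
        probes = common[chrom_of == chrom]
        if len(probes) == 0:
            raise ValidationError(f"no {chrom} probes shared between matrix and manifest")
        log.debug("%s: %d probes after intersection", chrom, len(probes))
        for metric in METRICS:
            source = getattr(matrix, metric)
            if source is None:
                raise ValidationError(f"matrix has no {metric} values")
            arr = source.loc[probes].to_numpy(dtype=float)
            edges = np.asarray(scheme.edges(metric))
            mask = ~np.isnan(arr)
            used = mask.sum(axis=0)
            if (used == 0).any():
                bad = samples[used == 0][0]
                raise ValidationError(
                    f"sample {bad!r} has no usable {chrom} {metric} values"
                )
            idx = _bin_indices(np.where(mask, arr, 0.0), edges)
            n_bins = len(edges) - 1
            counts = np.zeros((n_bins, arr.shape[1]))
            rows, cols = np.nonzero(mask)
            np.add.at(counts, (idx[rows, cols], cols), 1.0)
            props = counts / used
            tables[(chrom, metric)] = pd.DataFrame(
                props.T, index=samples, columns=list(edges[1:])
            )
            n_probes[(chrom, metric)] = pd.Series(used, index=samples)
    return ProfileTable(scheme=scheme, tables=tables, n_probes=n_probes)


def qc_filter(
    matrix: MethylationMatrix,
    annot: ProbeAnnotation,
    p_cutoff: float = 0.01,
    max_fail_frac: float = 0.05,
) -> pd.DataFrame:
    """Flag samples whose chrX probes fail detection too often.

    A chrX probe fails when its detection p-value is >= ``p_cutoff`` or is
    missing (an absent p-value conveys no confidence).  A sample passes iff
    the failing fraction is <= ``max_fail_frac`` — strictly more than the
    threshold fails, so exactly 5% is retained under the defaults.

    Returns a DataFrame indexed by sample ID with columns
    ``frac_chrX_failed`` and ``passed``.
    """
    if matrix.detp is None:
        raise ValidationError("QC requires detection p-values")
    common = matrix.probe_ids.intersection(annot.probe_ids)
    probes = common[annot.chromosome.loc[common] == "chrX"]
    if len(probes) == 0:
        raise ValidationError("no chrX probes shared between matrix and manifest")
    detp = matrix.detp.loc[probes]
    failed = (detp >= p_cutoff) | detp.isna()
    frac = failed.sum(axis=0) / len(probes)
    report = pd.DataFrame(
        {"frac_chrX_failed": frac, "passed": frac <= max_fail_frac}
    )
    report.index.name = "sample_id"
    log.info("QC: %d of %d samples passed", int(report["passed"].sum()), len(report))
    return report
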