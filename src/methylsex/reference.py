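"""Curated male/female reference panels and their fine-binned profiles.

A panel stores each reference sample's beta proportions over 100 fine bins of
width 0.01 and detection-p proportions over 18 decade bins (p <= 1e-17, then
one bin per decade up to 0.1 < p <= 1), per sex chromosome.  Because every
coarse scheme a user may request is a union of these fine bins, the panel can
be re-binned exactly — coarse proportions are sums of the contained fine
proportions — without revisiting the raw data.

``build_reference`` curates a panel from a labelled cohort: the chrX and chrY
feature blocks are clustered independently, samples whose two cluster
memberships agree with where the bulk of their own label sits are kept
("concordant"), and within each concordant sex group only the fraction of
samples closest to their cluster centre is retained, trimming borderline
profiles from the panel.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .estimator import pca_cluster
from .exceptions import EstimationError, SchemeAlignmentError, ValidationError
from .profiles import BinScheme, ProfileTable

log = logging.getLogger(__name__)

_CELLS = ("1/1", "1/2", "2/1", "2/2")
_PANEL_FILES = {
    ("chrX", "beta"): "chrX_beta.tsv",
    ("chrX", "detp"): "chrX_detp.tsv",
    ("chrY", "beta"): "chrY_beta.tsv",
    ("chrY", "detp"): "chrY_detp.tsv",
}
_META_FILE = "panel_meta.tsv"
_FORMAT_VERSION = 1


def _edge_indices(coarse: tuple[float, ...], fine: tuple[float, ...]) -> list[int]:
    """Index of each coarse edge within the fine edges, or raise.

    Matching is relative (rtol 1e-9, atol 1e-15): the decade detection-p
    edges span 17 orders of magnitude, so an absolute tolerance alone cannot
    separate neighbouring fine edges near zero.
    """
    fine_arr = np.asarray(fine)
    out = []
    for e in coarse:
        j = int(np.argmin(np.abs(fine_arr - e)))
        if not np.isclose(fine_arr[j], e, rtol=1e-9, atol=1e-15):
            raise SchemeAlignmentError(
                f"edge {e!r} does not coincide with any fine-panel edge"
            )
        out.append(j)
    return out


def rebin_profiles(profiles: ProfileTable, scheme: BinScheme) -> ProfileTable:
    """Re-bin a profile table to a coarser aligned scheme.

    Each coarse bin must be a union of consecutive fine bins (edges must
    coincide); its proportion is the exact sum of theirs, so row sums are
    preserved and no interpolation ever happens.
    """
    tables = {}
    for (chrom, metric), df in profiles.tables.items():
        fine_edges = profiles.scheme.edges(metric)
        coarse_edges = scheme.edges(metric)
        idxs = _edge_indices(coarse_edges, fine_edges)
        arr = df.to_numpy(dtype=float)
        coarse = np.add.reduceat(arr, idxs[:-1], axis=1)
        tables[(chrom, metric)] = pd.DataFrame(
            coarse, index=df.index, columns=list(coarse_edges[1:])
        )
    return ProfileTable(scheme=scheme, tables=tables, n_probes=dict(profiles.n_probes))


@dataclass
class ReferencePanel:
    """Fine-binned profiles of curated reference samples with sex labels.

    ``labels`` ('f'/'m') is aligned with ``profiles.sample_ids``; ``meta``
    records build provenance (seed, retention fraction, format version).
    """

    profiles: ProfileTable
    labels: pd.Series
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(str).str.lower()
        if not self.labels.index.equals(self.profiles.sample_ids):
            raise ValidationError("panel labels must align with profile sample IDs")
        bad = set(self.labels.unique()) - {"f", "m"}
        if bad:
            raise ValidationError(f"panel labels must be 'f'/'m', got {sorted(bad)}")
        counts = self.labels.value_counts()
        if counts.get("f", 0) < 2 or counts.get("m", 0) < 2:
            raise ValidationError("panel needs at least 2 reference samples per sex")
        for key, df in self.profiles.tables.items():
            sums = df.to_numpy(dtype=float).sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValidationError(f"panel table {key} rows do not sum to 1")

    def rebin(self, scheme: BinScheme) -> ProfileTable:
        return rebin_profiles(self.profiles, scheme)

    # -- serialisation: a diff-able tab-separated bundle -------------------

    def save(self, directory) -> None:
        """Write the panel bundle: ``panel_meta.tsv`` ('#key=value' header
        lines, then sample_id/sex rows) plus one samples x bins TSV per
        chromosome x metric whose header holds the bin upper edges."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        scheme = self.profiles.scheme
        with open(d / _META_FILE, "w") as fh:
            fh.write(f"#format_version={_FORMAT_VERSION}\n")
            for k in ("seed", "retention_fraction"):
                if k in self.meta:
                    fh.write(f"#{k}={self.meta[k]}\n")
            fh.write("#beta_edges=" + ",".join(f"{e:.17g}" for e in scheme.beta_edges) + "\n")
            fh.write("#detp_edges=" + ",".join(f"{e:.17g}" for e in scheme.detp_edges) + "\n")
            fh.write("sample_id\tsex\n")
            for sid, sex in self.labels.items():
                fh.write(f"{sid}\t{sex}\n")
        for key, fname in _PANEL_FILES.items():
            df = self.profiles.tables[key].copy()
            df.columns = [f"{c:.17g}" for c in df.columns]
            df.to_csv(d / fname, sep="\t", index_label="sample_id", float_format="%.17g")

    @classmethod
    def load(cls, directory) -> "ReferencePanel":
        d = Path(directory)
        meta_path = d / _META_FILE
        if not meta_path.exists():
            raise ValidationError(f"not a panel directory (missing {_META_FILE}): {d}")
        meta: dict = {}
        header_lines = 0
        with open(meta_path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                header_lines += 1
                k, _, v = line[1:].strip().partition("=")
                meta[k] = v
        for req in ("beta_edges", "detp_edges"):
            if req not in meta:
                raise ValidationError(f"panel metadata missing {req}")
        scheme = BinScheme(
            beta_edges=tuple(float(x) for x in meta.pop("beta_edges").split(",")),
            detp_edges=tuple(float(x) for x in meta.pop("detp_edges").split(",")),
        )
        labels_df = pd.read_csv(meta_path, sep="\t", skiprows=header_lines, dtype=str)
        labels = pd.Series(
            labels_df["sex"].to_numpy(), index=pd.Index(labels_df["sample_id"], name="sample_id")
        )
        tables = {}
        for key, fname in _PANEL_FILES.items():
            df = pd.read_csv(d / fname, sep="\t", index_col=0)
            edges = scheme.edges(key[1])
            if df.shape[1] != len(edges) - 1:
                raise ValidationError(f"{fname}: expected {len(edges) - 1} bins, got {df.shape[1]}")
            df.columns = list(edges[1:])
            df = df.loc[labels.index]
            tables[key] = df
        profiles = ProfileTable(scheme=scheme, tables=tables)
        for k in ("seed", "retention_fraction"):
            if k in meta:
                meta[k] = float(meta[k]) if k == "retention_fraction" else int(meta[k])
        return cls(profiles=profiles, labels=labels, meta=meta)


@dataclass
class ReferenceBuildResult:
    """Outcome of a panel build.

    ``concordance`` is the 2 x 4 table of labelled-sex counts per
    (chrX cluster / chrY cluster) cell; ``diagnostics`` records, per input
    sample, its clusters, concordance, distance to centre and whether it was
    retained.
    """

    panel: ReferencePanel
    concordance: pd.DataFrame
    diagnostics: pd.DataFrame


def build_reference(
    profiles: ProfileTable,
    labels: pd.Series,
    retention_fraction: float = 0.875,
    seed: int = 0,
) -> ReferenceBuildResult:
    """Curate a reference panel from a labelled cohort profiled at the fine
    scheme.

    Both sex-chromosome axes are clustered with :func:`pca_cluster` (the
    labelled samples acting as their own references).  A sample is concordant
    when, on both axes, it sits in the cluster that holds the majority of its
    own label.  Within each concordant sex group, the ``retention_fraction``
    of samples closest to their cluster centres — distance is the Euclidean
    norm over both axes' clustering spaces — is retained; exactly
    ``floor(retention_fraction * n)`` samples survive per group.
    """
    labels = pd.Series(labels).astype(str).str.lower()
    if not labels.index.equals(profiles.sample_ids):
        labels = labels.reindex(profiles.sample_ids)
    if labels.isna().any():
        raise ValidationError("every profiled sample needs an 'f'/'m' label")
    bad = set(labels.unique()) - {"f", "m"}
    if bad:
        raise ValidationError(f"labels must be 'f'/'m', got {sorted(bad)}")
    counts = labels.value_counts()
    if counts.get("f", 0) < 4 or counts.get("m", 0) < 4:
        raise ValidationError("need at least 4 labelled samples per sex")
    if not 0 < retention_fraction <= 1:
        raise ValidationError("retention_fraction must be in (0, 1]")

    res_x = pca_cluster(profiles.features("X"), labels, seed=int(seed) % (2**31), axis="X")
    res_y = pca_cluster(
        profiles.features("Y"), labels, seed=(int(seed) + 7919) % (2**31), axis="Y"
    )
    cx = res_x.assignments["cluster"]
    cy = res_y.assignments["cluster"]

    concordance = pd.DataFrame(0, index=["f", "m"], columns=list(_CELLS))
    cell = cx.astype(str) + "/" + cy.astype(str)
    for sex in ("f", "m"):
        vc = cell[labels == sex].value_counts()
        for c in _CELLS:
            concordance.loc[sex, c] = int(vc.get(c, 0))
    concordance.index.name = "label"

    # cluster holding the majority of each label, per axis
    majority_cell = {}
    for sex in ("f", "m"):
        mx = cx[labels == sex].mode().iat[0]
        my = cy[labels == sex].mode().iat[0]
        majority_cell[sex] = f"{mx}/{my}"
    if majority_cell["f"] == majority_cell["m"]:
        raise EstimationError("labelled sexes concentrate in the same cluster cell")

    dist = np.hypot(
        res_x.assignments["dist_to_centre"].to_numpy(),
        res_y.assignments["dist_to_centre"].to_numpy(),
    )
    dist = pd.Series(dist, index=profiles.sample_ids)
    concordant = pd.Series(
        [cell.loc[s] == majority_cell[labels.loc[s]] for s in profiles.sample_ids],
        index=profiles.sample_ids,
    )

    retained_ids: list = []
    for sex in ("f", "m"):
        group = profiles.sample_ids[(labels == sex) & concordant]
        n_keep = math.floor(retention_fraction * len(group))
        if n_keep < 2:
            raise EstimationError(
                f"retention leaves {n_keep} concordant {sex!r} samples (need >= 2)"
            )
        order = np.argsort(dist.loc[group].to_numpy(), kind="stable")
        retained_ids.extend(group[order[:n_keep]])
        log.info("retained %d of %d concordant %s samples", n_keep, len(group), sex)
    retained_index = profiles.sample_ids[profiles.sample_ids.isin(retained_ids)]

    panel = ReferencePanel(
        profiles=profiles.subset(retained_index),
        labels=labels.loc[retained_index],
        meta={
            "seed": int(seed),
            "retention_fraction": float(retention_fraction),
            "format_version": _FORMAT_VERSION,
        },
    )
    diagnostics = pd.DataFrame(
        {
            "label": labels,
            "cluster_x": cx,
            "cluster_y": cy,
            "concordant": concordant,
            "dist_to_centre": dist,
            "retained": profiles.sample_ids.isin(retained_ids),
        },
        index=profiles.sample_ids,
    )
    diagnostics.index.name = "sample_id"
    return ReferenceBuildResult(panel=panel, concordance=concordance, diagnostics=diagnostics)


def synthetic_reference_panel(
    n_per_sex: int = 100, retention_fraction: float = 0.875, seed: int = 0
) -> ReferencePanel:
    """A ready-to-use panel built from a synthetic labelled cohort.

    Deterministic in ``seed``: simulating ``n_per_sex`` XX and XY samples
    under the generator's default effect sizes, profiling them at the fine
    scheme and curating with :func:`build_reference` always reproduces the
    same panel.  The panel is synthetic — its metadata records this — and is
    meant for testing and for users without a labelled cohort of their own.
    """
    from .profiles import build_profiles
    from .synthetic import SimulationConfig, simulate_cohort

    cohort = simulate_cohort(SimulationConfig(n_xx=n_per_sex, n_xy=n_per_sex, seed=seed))
    profiles = build_profiles(cohort.matrix, cohort.annot, BinScheme.fine())
    labels = cohort.truth["sex_label"].str.lower()
    result = build_reference(
        profiles, labels, retention_fraction=retention_fraction, seed=seed
    )
    result.panel.meta["provenance"] = "synthetic"
    return result.panel
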