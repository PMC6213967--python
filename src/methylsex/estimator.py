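"""Sex calls from clustering of distribution profiles.

The estimation procedure anchors every test cohort to a labelled reference
panel: test-sample profiles are concatenated with the (re-binned) reference
profiles, the combined beta + detection-p feature block of each sex
chromosome is submitted to PCA, and k-means (k = 2) partitions the principal
component scores.  The sex meaning of a cluster is always derived from the
reference members it contains, never from the arbitrary cluster index, which
also makes the call robust to test cohorts heavily biased towards one sex.

Per axis each sample receives 'f' or 'm'; the combined call is 'F' when both
axes say 'f', 'M' when both say 'm', and 'N' when they conflict.  N-samples
are candidate mislabellings, mosaics or sex-chromosome aneuploidies: the
Klinefelter signature is a female-like chrX with a male-like chrY (f, m), the
Turner signature the reverse (m, f).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Mapping

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .exceptions import EstimationError, ValidationError
from .profiles import BinScheme, MethylationMatrix, ProbeAnnotation, build_profiles, qc_filter

if TYPE_CHECKING:  # pragma: no cover
    from .reference import ReferencePanel

log = logging.getLogger(__name__)

_REF_PREFIX = "ref::"
#: minimum fraction of one sex among a cluster's reference members before a
#: purity warning is attached to every call from that axis
PURITY_THRESHOLD = 0.90


@dataclass
class AxisResult:
    """Clustering outcome for one sex-chromosome axis.

    ``assignments`` is indexed by sample ID with columns ``cluster`` (1 =
    the cluster holding the majority of female references, 2 = the other),
    ``assigned_sex`` ('f'/'m', the majority reference sex of the cluster),
    ``pc1`` (first principal-component score, sign-oriented so the female
    reference mean is negative), ``dist_to_centre`` (Euclidean distance to
    the sample's k-means centroid in the clustered score space) and
    ``is_reference``.
    """

    axis: str
    assignments: pd.DataFrame
    purity: dict[int, float]
    warnings: list[str] = field(default_factory=list)


def pca_cluster(
    features: pd.DataFrame,
    ref_sex: pd.Series | Mapping[str, str],
    seed: int = 0,
    pc1_only: bool = False,
    n_init: int = 10,
    axis: str = "?",
) -> AxisResult:
    """PCA then 2-means on one axis' proportion features.

    ``features`` holds one row per sample (reference and test alike);
    ``ref_sex`` gives 'f'/'m' for reference rows and None/NaN for test rows.
    Columns are mean-centred (not variance-scaled: bin proportions are
    already commensurate); all principal components with non-negligible
    variance are retained and k-means runs on the full score matrix, which is
    a rotation of the centred feature space.  ``pc1_only`` restricts
    clustering to the first component instead.

    Raises :class:`EstimationError` when the reference samples do not split
    across the two clusters ("reference did not split").
    """
    if len(features) < 2:
        raise ValidationError("need at least 2 samples to cluster")
    ref = pd.Series(ref_sex).reindex(features.index)
    is_f = (ref == "f").to_numpy()
    is_m = (ref == "m").to_numpy()
    if is_f.sum() == 0 or is_m.sum() == 0:
        raise ValidationError("need at least one reference sample of each sex")

    X = features.to_numpy(dtype=float)
    pca = PCA()
    scores = pca.fit_transform(X)
    keep = pca.explained_variance_ > 1e-12
    if not keep.any():
        keep[0] = True
    S = scores[:, keep]
    if pc1_only:
        S = S[:, :1]

    km = KMeans(n_clusters=2, n_init=n_init, random_state=int(seed) % (2**31))
    raw = km.fit_predict(S)

    n_by = {}
    for c in (0, 1):
        nf = int((is_f & (raw == c)).sum())
        nm = int((is_m & (raw == c)).sum())
        if nf + nm == 0:
            raise EstimationError(
                f"axis {axis}: reference did not split (cluster without reference members)"
            )
        n_by[c] = (nf, nm)
    sex_of = {}
    for c, (nf, nm) in n_by.items():
        if nf == nm:
            raise EstimationError(f"axis {axis}: reference did not split (tied cluster)")
        sex_of[c] = "f" if nf > nm else "m"
    if sex_of[0] == sex_of[1]:
        raise EstimationError(
            f"axis {axis}: reference did not split (both clusters majority {sex_of[0]!r})"
        )

    warnings_: list[str] = []
    purity = {}
    female_raw = 0 if sex_of[0] == "f" else 1
    for c, (nf, nm) in n_by.items():
        p = max(nf, nm) / (nf + nm)
        purity[1 if c == female_raw else 2] = p
        if p < PURITY_THRESHOLD:
            warnings_.append(
                f"axis {axis}: cluster {1 if c == female_raw else 2} reference purity "
                f"{p:.2f} below {PURITY_THRESHOLD:.2f}"
            )
    for w in warnings_:
        log.warning(w)

    pc1 = scores[:, 0].copy()
    if pc1[is_f].mean() > 0:
        pc1 = -pc1
    dist = np.linalg.norm(S - km.cluster_centers_[raw], axis=1)

    assignments = pd.DataFrame(
        {
            "cluster": np.where(raw == female_raw, 1, 2),
            "assigned_sex": [sex_of[c] for c in raw],
            "pc1": pc1,
            "dist_to_centre": dist,
            "is_reference": is_f | is_m,
        },
        index=features.index,
    )
    return AxisResult(axis=axis, assignments=assignments, purity=purity, warnings=warnings_)


def combine_calls(sex_x: str, sex_y: str) -> str:
    """Combine the per-axis sexes into the final call.

    (f, f) -> 'F'; (m, m) -> 'M'; any conflict -> 'N'.
    """
    for v in (sex_x, sex_y):
        if v not in ("f", "m"):
            raise ValidationError(f"per-axis sex must be 'f' or 'm', got {v!r}")
    if sex_x == sex_y:
        return "F" if sex_x == "f" else "M"
    return "N"


@dataclass
class EstimationResult:
    """Per-test-sample calls plus the reference coordinates of the same run.

    ``calls`` is indexed by sample ID with columns ``sex_chrX``, ``sex_chrY``,
    ``predicted`` (F/M/N), ``pc1_x``, ``pc1_y``, ``frac_chrX_detp_failed``,
    ``qc_passed`` and ``warnings``.  ``ref_coords`` carries sex, pc1_x and
    pc1_y for the panel samples so plots can underlay the reference.
    """

    calls: pd.DataFrame
    ref_coords: pd.DataFrame
    warnings: list[str] = field(default_factory=list)


def estimate_sex(
    test: MethylationMatrix,
    annot: ProbeAnnotation,
    panel: "ReferencePanel",
    scheme: BinScheme | None = None,
    seed: int = 0,
    pc1_only: bool = False,
) -> EstimationResult:
    """Run the full estimation procedure on a test cohort.

    Builds test profiles under ``scheme``, re-bins the reference panel to the
    same scheme, concatenates the two tables, clusters each sex-chromosome
    axis, and combines the per-axis assignments into F/M/N calls.  QC results
    (chrX detection-p failure fraction) are attached but never drop samples
    here: flagging is the caller's decision.
    """
    scheme = scheme or BinScheme.default()
    if len(test.sample_ids) == 0:
        raise ValidationError("empty test set")
    test_prof = build_profiles(test, annot, scheme)
    ref_prof = panel.rebin(scheme)

    qc = None
    if test.detp is not None:
        qc = qc_filter(test, annot)

    axis_results: dict[str, AxisResult] = {}
    all_warnings: list[str] = []
    for i, ax in enumerate(("X", "Y")):
        ref_feats = ref_prof.features(ax)
        ref_feats.index = [_REF_PREFIX + str(s) for s in ref_feats.index]
        test_feats = test_prof.features(ax)
        if test_feats.index.astype(str).str.startswith(_REF_PREFIX).any():
            raise ValidationError(f"test sample IDs may not start with {_REF_PREFIX!r}")
        feats = pd.concat([ref_feats, test_feats])
        ref_sex = pd.Series(index=feats.index, dtype=object)
        ref_sex.iloc[: len(ref_feats)] = panel.labels.to_numpy()
        res = pca_cluster(
            feats,
            ref_sex,
            seed=(int(seed) + 7919 * i) % (2**31),
            pc1_only=pc1_only,
            axis=ax,
        )
        axis_results[ax] = res
        all_warnings.extend(res.warnings)

    ax_x = axis_results["X"].assignments
    ax_y = axis_results["Y"].assignments
    test_ids = test_prof.sample_ids
    sex_x = ax_x.loc[test_ids, "assigned_sex"]
    sex_y = ax_y.loc[test_ids, "assigned_sex"]
    calls = pd.DataFrame(
        {
            "sex_chrX": sex_x,
            "sex_chrY": sex_y,
            "predicted": [combine_calls(a, b) for a, b in zip(sex_x, sex_y)],
            "pc1_x": ax_x.loc[test_ids, "pc1"],
            "pc1_y": ax_y.loc[test_ids, "pc1"],
        },
        index=test_ids,
    )
    if qc is not None:
        calls["frac_chrX_detp_failed"] = qc["frac_chrX_failed"]
        calls["qc_passed"] = qc["passed"]
    else:
        calls["frac_chrX_detp_failed"] = np.nan
        calls["qc_passed"] = True
    calls["warnings"] = ";".join(all_warnings)
    calls.index.name = "sample_id"

    ref_ids = [_REF_PREFIX + str(s) for s in panel.labels.index]
    ref_coords = pd.DataFrame(
        {
            "sex": panel.labels.to_numpy(),
            "pc1_x": ax_x.loc[ref_ids, "pc1"].to_numpy(),
            "pc1_y": ax_y.loc[ref_ids, "pc1"].to_numpy(),
        },
        index=panel.labels.index,
    )
    ref_coords.index.name = "sample_id"
    n_pred = calls["predicted"].value_counts().to_dict()
    log.info("estimated %d samples: %s", len(calls), n_pred)
    return EstimationResult(calls=calls, ref_coords=ref_coords, warnings=all_warnings)


@dataclass
class MismatchReport:
    """Discordant samples (prediction contradicts a firm label) and
    N-samples (reported separately, never counted as discordant)."""

    discordant: pd.DataFrame
    n_samples: pd.DataFrame


def detect_label_mismatch(
    calls: pd.DataFrame, labels: pd.Series | Mapping[str, str]
) -> MismatchReport:
    """Compare F/M predictions against recorded sex labels.

    ``labels`` maps sample ID to 'F', 'M' or 'unknown' (case-insensitive).
    A sample is discordant when its prediction is F or M and differs from a
    firm label.  Samples predicted N are listed separately with their label.
    Label IDs absent from ``calls`` are an error.
    """
    lab = pd.Series(labels).astype(str).str.upper()
    unknown_ids = lab.index.difference(calls.index)
    if len(unknown_ids):
        raise ValidationError(f"labels refer to unknown sample IDs: {list(unknown_ids)[:5]}")
    bad = set(lab.unique()) - {"F", "M", "UNKNOWN"}
    if bad:
        raise ValidationError(f"labels must be F/M/unknown, got {sorted(bad)}")

    lab = lab.reindex(calls.index).fillna("UNKNOWN")
    pred = calls["predicted"]
    firm = lab.isin(["F", "M"])
    disc_mask = pred.isin(["F", "M"]) & firm & (pred != lab)
    discordant = pd.DataFrame({"label": lab[disc_mask], "predicted": pred[disc_mask]})
    n_mask = pred == "N"
    n_samples = pd.DataFrame({"label": lab[n_mask], "predicted": pred[n_mask]})
    for df in (discordant, n_samples):
        df.index.name = "sample_id"
    return MismatchReport(discordant=discordant, n_samples=n_samples)
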