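"""Readers and writers for the tab-separated interchange formats.

Matrices follow a GEO series-matrix-like layout: first column probe ID,
header row of sample IDs, tab-separated, with gzip handled transparently by
file extension.  Blank and NA tokens become missing values; duplicate IDs,
ragged rows and values outside [0, 1] are rejected with the offending line
number.  Values round-trip at 6 significant digits.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .profiles import MethylationMatrix, ProbeAnnotation

log = logging.getLogger(__name__)

NA_TOKENS = ("", "NA", "NaN", "nan", "null", "NULL")
FLOAT_FORMAT = "%.6g"


def _header_fields(path: Path) -> list[str]:
    """First line of a (possibly gzipped) TSV, split on tabs."""
    import gzip

    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        return fh.readline().rstrip("\n").split("\t")


def read_matrix(path) -> pd.DataFrame:
    """Read one half (beta or detp) of a methylation matrix.

    Returns a probes x samples DataFrame of floats in [0, 1] with NaN for
    missing entries.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    # pandas silently renames duplicate header fields, so check them raw
    header = _header_fields(path)[1:]
    if len(set(header)) != len(header):
        dup = next(h for h in header if header.count(h) > 1)
        raise ValidationError(f"{path}: duplicate sample ID {dup!r}")
    try:
        raw = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            dtype=str,
            keep_default_na=False,
            na_values=list(NA_TOKENS),
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: malformed table ({exc})") from exc
    if raw.index.has_duplicates:
        dup = raw.index[raw.index.duplicated()][0]
        raise ValidationError(f"{path}: duplicate probe ID {dup!r}")
    if raw.columns.has_duplicates:
        dup = raw.columns[raw.columns.duplicated()][0]
        raise ValidationError(f"{path}: duplicate sample ID {dup!r}")
    values = raw.apply(pd.to_numeric, errors="coerce")
    unparsable = values.isna() & raw.notna()
    if unparsable.to_numpy().any():
        r, c = np.argwhere(unparsable.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric value {raw.iat[r, c]!r} for probe {raw.index[r]!r} "
            f"(line {r + 2})"
        )
    out_of_range = (values < 0) | (values > 1)
    if out_of_range.to_numpy().any():
        r, c = np.argwhere(out_of_range.to_numpy())[0]
        raise ValidationError(
            f"{path}: value {values.iat[r, c]} outside [0, 1] for probe "
            f"{values.index[r]!r} (line {r + 2})"
        )
    values.index.name = "probe_id"
    return values


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="probe_id", float_format=FLOAT_FORMAT, na_rep="NA")


def read_manifest(path) -> ProbeAnnotation:
    """Read a probe manifest: columns ``probe_id`` and ``chromosome``.

    Chromosome tokens "X"/"chrX" and "Y"/"chrY" (any case) map to the sex
    chromosomes; anything else is autosomal.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("probe_id", "chromosome"):
        if col not in df.columns:
            raise ValidationError(f"{path}: manifest must have a {col!r} column")
    series = pd.Series(
        df["chromosome"].to_numpy(), index=pd.Index(df["probe_id"], name="probe_id")
    )
    annot = ProbeAnnotation.from_tokens(series)
    log.info("manifest: %s", annot.counts())
    return annot


def write_manifest(annot: ProbeAnnotation, path) -> None:
    df = pd.DataFrame({"chromosome": annot.chromosome})
    df.to_csv(path, sep="\t", index_label="probe_id")


def read_labels(path) -> pd.Series:
    """Read a sample-sheet label file: columns ``sample_id`` and ``sex``
    with values F/M/unknown (case-insensitive)."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "sex"):
        if col not in df.columns:
            raise ValidationError(f"{path}: labels must have a {col!r} column")
    labels = pd.Series(
        df["sex"].str.strip().str.upper().to_numpy(),
        index=pd.Index(df["sample_id"], name="sample_id"),
    )
    bad = set(labels.unique()) - {"F", "M", "UNKNOWN"}
    if bad:
        raise ValidationError(f"{path}: labels must be F/M/unknown, got {sorted(bad)}")
    if labels.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate sample IDs")
    return labels


def write_labels(labels: pd.Series, path) -> None:
    pd.DataFrame({"sex": labels}).to_csv(path, sep="\t", index_label="sample_id")


def read_methylation(beta_path, detp_path) -> MethylationMatrix:
    """Read and align the beta and detection-p halves of a matrix."""
    beta = read_matrix(beta_path) if beta_path is not None else None
    detp = read_matrix(detp_path) if detp_path is not None else None
    return MethylationMatrix.from_parts(beta, detp)


RESULT_COLUMNS = (
    "predicted_sex",
    "sex_chrX",
    "sex_chrY",
    "X.PC1",
    "Y.PC1",
    "frac_chrX_detp_failed",
    "qc_passed",
    "warnings",
)


def write_results(calls: pd.DataFrame, path) -> None:
    """Write estimation calls as the results TSV (one row per test sample)."""
    out = pd.DataFrame(
        {
            "predicted_sex": calls["predicted"],
            "sex_chrX": calls["sex_chrX"],
            "sex_chrY": calls["sex_chrY"],
            "X.PC1": calls["pc1_x"],
            "Y.PC1": calls["pc1_y"],
            "frac_chrX_detp_failed": calls["frac_chrX_detp_failed"],
            "qc_passed": calls["qc_passed"],
            "warnings": calls["warnings"],
        },
        index=calls.index,
    )
    out.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_results(path) -> pd.DataFrame:
    """Read a results TSV back into the internal calls layout."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: results file missing columns {sorted(missing)}")
    calls = pd.DataFrame(
        {
            "sex_chrX": df["sex_chrX"],
            "sex_chrY": df["sex_chrY"],
            "predicted": df["predicted_sex"],
            "pc1_x": df["X.PC1"],
            "pc1_y": df["Y.PC1"],
            "frac_chrX_detp_failed": df["frac_chrX_detp_failed"],
            "qc_passed": df["qc_passed"],
            "warnings": df["warnings"].fillna(""),
        },
        index=df.index,
    )
    calls.index.name = "sample_id"
    return calls


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def write_ref_coords(ref_coords: pd.DataFrame, path) -> None:
    ref_coords.to_csv(path, sep="\t", index_label="sample_id", float_format=FLOAT_FORMAT)


def read_ref_coords(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    for col in ("sex", "pc1_x", "pc1_y"):
        if col not in df.columns:
            raise ValidationError(f"{path}: reference coordinates missing column {col!r}")
    return df
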