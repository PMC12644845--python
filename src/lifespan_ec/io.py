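"""Readers/writers, data model, and logging for on-disk artifacts.

All artifacts are plain delimited text (TSV, UTF-8, ``.`` decimal, header
row mandatory) so every pipeline stage is inspectable and replaceable.
Region order in the parcellation file is canonical: series and EC matrices
are reordered to it on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("lifespan_ec")

#: Canonical ordering of the seven functional networks of the 7-network
#: cortical parcellation: visual, somatomotor, dorsal attention, ventral
#: attention/salience, limbic, frontoparietal control, default mode.
SEVEN_NETWORKS = ("VIS", "SM", "DAN", "VAN", "LIM", "FPC", "DMN")

#: Region counts per network in the Schaefer-400 / 7-network assignment.
SEVEN_NETWORK_SIZES = {
    "VIS": 61,
    "SM": 77,
    "DAN": 46,
    "VAN": 47,
    "LIM": 26,
    "FPC": 52,
    "DMN": 91,
}


def configure_logging(level: str = "INFO", logfile: str | Path | None = None) -> None:
    """Route package logging to stderr and, optionally, a file."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(levelname)s %(name)s: %(message)s",
        handlers=handlers,
        force=True,
    )


# ---------------------------------------------------------------------------
# Parcellation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Parcellation:
    """Region-to-network assignment with a fixed canonical region order."""

    region_ids: tuple[str, ...]
    network_of: Mapping[str, str]
    networks: tuple[str, ...]

    def __post_init__(self) -> None:
        missing = [r for r in self.region_ids if r not in self.network_of]
        if missing:
            raise ValueError(f"regions without a network assignment: {missing[:5]}")
        counts = self.counts()
        if any(c <= 0 for c in counts.values()):
            raise ValueError("every network must contain at least one region")
        if sum(counts.values()) != len(self.region_ids):
            raise ValueError("network counts do not sum to the region total")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def counts(self) -> dict[str, int]:
        out = {n: 0 for n in self.networks}
        for r in self.region_ids:
            out[self.network_of[r]] += 1
        return out

    def membership(self) -> np.ndarray:
        """Network index (position in ``networks``) per region, in order."""
        idx = {n: i for i, n in enumerate(self.networks)}
        return np.array([idx[self.network_of[r]] for r in self.region_ids])

    def region_indices(self, network: str) -> np.ndarray:
        return np.flatnonzero(self.membership() == self.networks.index(network))


def _order_networks(names: Iterable[str]) -> tuple[str, ...]:
    names = list(dict.fromkeys(names))
    if set(names) <= set(SEVEN_NETWORKS):
        return tuple(n for n in SEVEN_NETWORKS if n in names)
    return tuple(names)


def read_parcellation(path: str | Path) -> Parcellation:
    """Read a two-column (region_id, network) TSV table.

    Duplicate region ids and empty network names are hard errors.  When
    the seven canonical network names are present the network order is
    VIS, SM, DAN, VAN, LIM, FPC, DMN; otherwise file order is kept.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (region_id, network)")
    region_col, network_col = df.columns[:2]
    regions = df[region_col].tolist()
    networks = df[network_col].tolist()
    dups = df[region_col][df[region_col].duplicated()].tolist()
    if dups:
        raise ValueError(f"{path}: duplicate region ids {sorted(set(dups))[:5]}")
    if any(pd.isna(n) or str(n).strip() == "" for n in networks):
        raise ValueError(f"{path}: empty or missing network name")
    return Parcellation(
        region_ids=tuple(regions),
        network_of=dict(zip(regions, networks)),
        networks=_order_networks(networks),
    )


def write_parcellation(parcellation: Parcellation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "region_id": parcellation.region_ids,
            "network": [parcellation.network_of[r] for r in parcellation.region_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def reference_parcellation(sizes: Mapping[str, int] | None = None) -> Parcellation:
    """Synthetic stand-in for the Schaefer-400 / 7-network assignment.

    Region counts per network match the published atlas (61, 77, 46, 47,
    26, 52, 91 — total 400); region ids are synthetic labels of the form
    ``VIS_001`` since the atlas label table itself is not bundled.
    """
    sizes = dict(sizes or SEVEN_NETWORK_SIZES)
    region_ids: list[str] = []
    network_of: dict[str, str] = {}
    for net in sizes:
        for i in range(sizes[net]):
            rid = f"{net}_{i + 1:03d}"
            region_ids.append(rid)
            network_of[rid] = net
    return Parcellation(
        region_ids=tuple(region_ids),
        network_of=network_of,
        networks=_order_networks(sizes.keys()),
    )


# ---------------------------------------------------------------------------
# BOLD runs
# ---------------------------------------------------------------------------


@dataclass
class BoldRun:
    """One scan's regional time series plus its metadata.

    ``series`` is a T x R array whose column order matches the
    parcellation's region order.  ``sex`` is coded +1 male / -1 female.
    """

    subject_id: str
    age: float
    sex: int
    site: str
    tr: float
    series: np.ndarray
    region_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.ndim != 2 or self.series.shape[0] < 2:
            raise ValueError("series must be a T x R matrix with T >= 2")
        if not np.all(np.isfinite(self.series)):
            raise ValueError("series contains non-finite values")
        if self.age < 0:
            raise ValueError("age must be non-negative")
        if self.tr <= 0:
            raise ValueError("TR must be positive")
        if self.sex not in (+1, -1):
            raise ValueError("sex must be coded +1 (male) or -1 (female)")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[0]

    @property
    def n_regions(self) -> int:
        return self.series.shape[1]


_SEX_CODES = {
    "m": 1, "male": 1, "1": 1, "+1": 1,
    "f": -1, "female": -1, "-1": -1,
}


def normalize_sex(value: object) -> int:
    """Normalize M/F, male/female, or +/-1 codings to +1 / -1."""
    if isinstance(value, (int, np.integer, float, np.floating)):
        if value in (1, -1):
            return int(value)
        raise ValueError(f"unrecognized sex code {value!r}")
    key = str(value).strip().lower()
    if key in _SEX_CODES:
        return _SEX_CODES[key]
    raise ValueError(f"unrecognized sex code {value!r}")


def read_bold_run(
    series_path: str | Path,
    manifest_row: Mapping[str, object],
    parcellation: Parcellation,
) -> BoldRun:
    """Read one series TSV (header = region labels, rows = time points).

    Columns are reordered to the parcellation's canonical order; a label
    mismatch or non-numeric cell is a hard error.  No mean-centering is
    applied here — the estimation stage decides.
    """
    df = pd.read_csv(series_path, sep="\t")
    have = set(df.columns)
    want = set(parcellation.region_ids)
    if have != want:
        missing = sorted(want - have)
        extra = sorted(have - want)
        raise ValueError(
            f"{series_path}: region labels do not match parcellation "
            f"(missing {missing[:5]}, unexpected {extra[:5]})"
        )
    df = df[list(parcellation.region_ids)]
    try:
        series = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce")
            if bad.isna().any():
                row = int(bad.isna().idxmax())
                raise ValueError(
                    f"{series_path}: non-numeric value at row {row}, column {col!r}"
                ) from None
        raise
    return BoldRun(
        subject_id=str(manifest_row["subject_id"]),
        age=float(manifest_row["age"]),
        sex=normalize_sex(manifest_row["sex"]),
        site=str(manifest_row["site"]),
        tr=float(manifest_row["tr"]),
        series=series,
        region_ids=parcellation.region_ids,
    )


def write_bold_series(series: np.ndarray, region_ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame(np.asarray(series), columns=list(region_ids)).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


# ---------------------------------------------------------------------------
# Cohort manifests
# ---------------------------------------------------------------------------


@dataclass
class CohortManifest:
    """Table of scans: subject_id, age, sex, site, tr, series_path, mean_fd."""

    table: pd.DataFrame

    REQUIRED = ("subject_id", "age", "sex", "site", "series_path")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"manifest missing required column {col!r}")
        ages = self.table["age"].to_numpy(dtype=float)
        if not np.all(np.isfinite(ages)) or np.any(ages < 0):
            raise ValueError("manifest ages must be finite and non-negative")
        pairs = self.table[["subject_id", "series_path"]]
        if pairs.duplicated().any():
            raise ValueError("duplicate (subject_id, series_path) pairs in manifest")
        self.table = self.table.copy()
        self.table["sex"] = [normalize_sex(s) for s in self.table["sex"]]

    def __len__(self) -> int:
        return len(self.table)

    def rows(self):
        return (row for _, row in self.table.iterrows())


def read_manifest(path: str | Path) -> CohortManifest:
    sep = "," if str(path).endswith(".csv") else "\t"
    return CohortManifest(pd.read_csv(path, sep=sep))


def write_manifest(manifest: CohortManifest, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    manifest.table.to_csv(path, sep=sep, index=False, float_format="%.12g")


def filter_manifest_fd(manifest: CohortManifest, threshold: float = 0.5) -> CohortManifest:
    """Drop scans whose mean framewise displacement exceeds ``threshold`` mm.

    Scans at exactly the threshold are kept (only values *exceeding* the
    cutoff are motion-excluded); rows without a mean_fd value are kept
    and logged.
    """
    if threshold <= 0:
        raise ValueError("FD threshold must be positive")
    table = manifest.table
    if "mean_fd" not in table.columns:
        logger.warning("manifest has no mean_fd column; FD filter skipped")
        return manifest
    fd = pd.to_numeric(table["mean_fd"], errors="coerce")
    n_missing = int(fd.isna().sum())
    if n_missing:
        logger.info("FD filter: %d rows lack mean_fd and are kept", n_missing)
    keep = fd.isna() | (fd <= threshold)
    n_removed = int((~keep).sum())
    logger.info("FD filter: removed %d of %d scans (mean_fd > %g mm)", n_removed, len(table), threshold)
    if keep.sum() == 0:
        logger.warning("FD filter removed every scan")
    return CohortManifest(table[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# EC matrices
# ---------------------------------------------------------------------------


@dataclass
class ECMatrix:
    """Directed R x R effective-connectivity matrix.

    Entry (i, j) is the signed influence of source region j on target
    region i (rows collect incoming connections); positive entries are
    excitatory, negative inhibitory.
    """

    values: np.ndarray
    region_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        r = len(self.region_ids)
        if self.values.shape != (r, r):
            raise ValueError(f"EC matrix shape {self.values.shape} != ({r}, {r})")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("EC matrix contains non-finite entries")

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)


def read_ec_matrix(path: str | Path, parcellation: Parcellation | None = None) -> ECMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if parcellation is not None:
        order = list(parcellation.region_ids)
        if set(df.columns) != set(order):
            raise ValueError(f"{path}: EC matrix labels do not match parcellation")
        df = df.loc[order, order]
    return ECMatrix(values=df.to_numpy(dtype=float), region_ids=tuple(df.columns))


def write_ec_matrix(ec: ECMatrix, path: str | Path) -> None:
    pd.DataFrame(ec.values, index=list(ec.region_ids), columns=list(ec.region_ids)).to_csv(
        path, sep="\t", float_format="%.17g"
    )
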