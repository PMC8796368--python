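"""Readers, writers and preprocessing for array methylation data.

Covers the tabular formats the pipeline consumes (methylation matrix,
probe manifest, sample sheet), the beta -> M logit2 transform, call-rate
filtering, population mean/variance normalization and splitting of the
residual matrix into per-(sample, chromosome) tracks.

Conventions: matrices are probes x samples with a header row of sample
ids; manifests use 1-based base-pair positions on autosomes 1-22;
missing cells use a configurable sentinel (default empty/NA).  The
pipeline assumes probe-type (design I/II) normalization such as BMIQ has
already been applied upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger("methdep")

DEFAULT_MIN_TRACK_SITES = 50

__all__ = [
    "MethylationMatrix",
    "ProbeManifest",
    "SampleSheet",
    "ChromosomeTrack",
    "read_matrix",
    "write_matrix",
    "read_manifest",
    "read_sample_sheet",
    "beta_to_m",
    "m_to_beta",
    "call_rate_filter",
    "population_normalize",
    "split_by_chromosome",
]


@dataclass
class MethylationMatrix:
    """Probes x samples value grid with a missingness mask.

    ``values`` is float with NaN marking missing entries;
    ``value_scale`` is one of {"beta", "M", "residual"}.
    """

    probe_ids: pd.Index
    sample_ids: pd.Index
    values: np.ndarray
    value_scale: str = "beta"

    def __post_init__(self) -> None:
        self.probe_ids = pd.Index(self.probe_ids)
        self.sample_ids = pd.Index(self.sample_ids)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"value grid shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        for name, idx in (("probe", self.probe_ids), ("sample", self.sample_ids)):
            if idx.has_duplicates:
                dups = idx[idx.duplicated()].unique().tolist()
                raise ValueError(f"duplicate {name} ids: {dups[:5]}")
        if self.value_scale not in {"beta", "M", "residual"}:
            raise ValueError(f"unknown value_scale {self.value_scale!r}")
        if self.value_scale == "beta":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() <= 0.0 or finite.max() >= 1.0):
                raise ValueError("beta-scale values must lie strictly in (0, 1)")

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.probe_ids, columns=self.sample_ids)


@dataclass
class ChromosomeTrack:
    """One sample's residual values at sorted positions on one chromosome."""

    sample_id: str
    chromosome: int
    positions: np.ndarray
    residuals: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.residuals = np.asarray(self.residuals, dtype=float)
        if self.positions.shape != self.residuals.shape:
            raise ValueError("positions and residuals must have equal length")
        if self.positions.size > 1 and np.any(np.diff(self.positions) <= 0):
            raise ValueError("track positions must be strictly increasing")

    @property
    def n_sites(self) -> int:
        return self.positions.size


@dataclass
class ProbeManifest:
    """Probe annotation: chromosome (1-22), 1-based position, island flag."""

    table: pd.DataFrame

    REQUIRED = ("probe_id", "chrom", "pos", "island")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        t = self.table.copy()
        t["chrom"] = t["chrom"].astype(int)
        t["pos"] = t["pos"].astype(int)
        t["island"] = t["island"].astype(bool)
        if t["probe_id"].duplicated().any():
            dups = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
            raise ValueError(f"duplicate probe ids in manifest: {dups[:5]}")
        bad = ~t["chrom"].isin(range(1, 23))
        if bad.any():
            raise ValueError(
                f"manifest contains non-autosomal chromosome labels: "
                f"{sorted(t.loc[bad, 'chrom'].unique().tolist())}"
            )
        if (t["pos"] < 1).any():
            raise ValueError("manifest positions must be >= 1 (1-based)")
        self.table = t.reset_index(drop=True)


@dataclass
class SampleSheet:
    """Sample metadata: family/pair structure, zygosity, sex, age, batches."""

    table: pd.DataFrame

    REQUIRED = (
        "sample_id",
        "family_id",
        "pair_id",
        "zygosity",
        "sex",
        "age",
        "plate",
        "beadchip",
    )

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        t = self.table.copy()
        if t["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in sample sheet")
        bad_zyg = ~t["zygosity"].isin(["MZ", "DZ"])
        if bad_zyg.any():
            raise ValueError(
                f"zygosity must be MZ or DZ, got {t.loc[bad_zyg, 'zygosity'].unique()}"
            )
        self.table = t.reset_index(drop=True)

    def co_twin_pairs(self) -> set[frozenset]:
        """Set of true co-twin pairs (as frozensets of sample ids)."""
        pairs = set()
        for _, grp in self.table.groupby("pair_id"):
            ids = grp["sample_id"].tolist()
            if len(ids) == 2:
                pairs.add(frozenset(ids))
        return pairs


# ---------------------------------------------------------------------------
# readers / writers


def read_matrix(
    path,
    delimiter: str = "\t",
    na_values: Iterable[str] = ("", "NA", "NaN"),
    value_scale: str = "beta",
) -> MethylationMatrix:
    """Read a probes x samples matrix from delimited text.

    First column holds probe ids, header row holds sample ids.  Raises a
    parse error naming the offending row/column on duplicate ids or
    non-numeric cells.
    """
    df = pd.read_csv(
        path,
        sep=delimiter,
        index_col=0,
        na_values=list(na_values),
        keep_default_na=False,
        float_precision="round_trip",
    )
    for col in df.columns:
        nonnum = pd.to_numeric(df[col], errors="coerce")
        bad = nonnum.isna() & df[col].notna()
        if bad.any():
            probe = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric cell at probe {probe!r}, sample {col!r} in {path}"
            )
        df[col] = nonnum
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate probe id {dup!r} in {path}")
    return MethylationMatrix(
        probe_ids=df.index,
        sample_ids=df.columns,
        values=df.to_numpy(dtype=float),
        value_scale=value_scale,
    )


def write_matrix(
    matrix: MethylationMatrix, path, delimiter: str = "\t", na_rep: str = "NA"
) -> None:
    """Write a matrix as delimited text with full float precision."""
    # shortest round-trip float repr keeps read(write(m)) exact
    df = matrix.to_frame()
    df.index.name = "probe_id"
    df.to_csv(path, sep=delimiter, na_rep=na_rep)


def read_manifest(path, delimiter: str = ",") -> ProbeManifest:
    return ProbeManifest(pd.read_csv(path, sep=delimiter))


def read_sample_sheet(path, delimiter: str = ",") -> SampleSheet:
    return SampleSheet(pd.read_csv(path, sep=delimiter))


# ---------------------------------------------------------------------------
# preprocessing


def beta_to_m(matrix: MethylationMatrix) -> MethylationMatrix:
    """logit2 transform: v -> log2(v / (1 - v)); beta scale to M scale."""
    if matrix.value_scale != "beta":
        raise ValueError(f"expected beta-scale matrix, got {matrix.value_scale!r}")
    vals = matrix.values
    with np.errstate(invalid="ignore"):
        bad = np.isfinite(vals) & ((vals <= 0.0) | (vals >= 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"beta value out of (0,1) at probe {matrix.probe_ids[i]!r}, "
            f"sample {matrix.sample_ids[j]!r}"
        )
    m = np.log2(vals / (1.0 - vals))
    return MethylationMatrix(matrix.probe_ids, matrix.sample_ids, m, "M")


def m_to_beta(values: np.ndarray) -> np.ndarray:
    """Inverse logit2: M -> 2^M / (1 + 2^M), numerically stable."""
    v = np.asarray(values, dtype=float)
    out = np.empty_like(v)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-v[pos]))
    e = np.exp2(v[~pos])
    out[~pos] = e / (1.0 + e)
    return out


@dataclass
class FilterReport:
    n_probes_in: int
    n_probes_retained: int
    dropped_probe_ids: list = field(default_factory=list)


def call_rate_filter(
    matrix: MethylationMatrix, min_rate: float = 0.95
) -> tuple[MethylationMatrix, FilterReport]:
    """Retain probes whose non-missing fraction across samples >= min_rate."""
    if not 0.0 < min_rate <= 1.0:
        raise ValueError(f"min_rate must be in (0, 1], got {min_rate}")
    if matrix.n_probes == 0 or matrix.n_samples == 0:
        raise ValueError("cannot filter an empty matrix")
    call_rate = np.isfinite(matrix.values).mean(axis=1)
    keep = call_rate >= min_rate
    report = FilterReport(
        n_probes_in=matrix.n_probes,
        n_probes_retained=int(keep.sum()),
        dropped_probe_ids=matrix.probe_ids[~keep].tolist(),
    )
    out = MethylationMatrix(
        matrix.probe_ids[keep],
        matrix.sample_ids,
        matrix.values[keep],
        matrix.value_scale,
    )
    return out, report


def population_normalize(
    matrix: MethylationMatrix,
) -> tuple[MethylationMatrix, pd.DataFrame]:
    """Center and scale each probe by its cross-sample mean and sample sd.

    The unbiased (n-1) sample sd is used so that unit-variance residuals
    match the sigma^2 = 1 prior calibration.  Probes with fewer than two
    observations or zero variance are dropped (logged, not an error).
    Returns the residual-scale matrix and a per-probe mean/sd table.
    """
    if matrix.value_scale != "M":
        raise ValueError(f"expected M-scale matrix, got {matrix.value_scale!r}")
    vals = matrix.values
    n_obs = np.isfinite(vals).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.nanmean(vals, axis=1)
        sds = np.nanstd(vals, axis=1, ddof=1)
    keep = (n_obs >= 2) & np.isfinite(sds) & (sds > 0)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning(
            "population_normalize: dropping %d probes with <2 observations or zero sd",
            n_drop,
        )
    resid = (vals[keep] - means[keep, None]) / sds[keep, None]
    stats = pd.DataFrame(
        {"probe_id": matrix.probe_ids, "mean": means, "sd": sds, "n_obs": n_obs,
         "retained": keep}
    )
    out = MethylationMatrix(
        matrix.probe_ids[keep], matrix.sample_ids, resid, "residual"
    )
    return out, stats


def split_by_chromosome(
    matrix: MethylationMatrix,
    manifest: ProbeManifest,
    min_sites: int = DEFAULT_MIN_TRACK_SITES,
) -> list[ChromosomeTrack]:
    """Split a residual matrix into per-(sample, chromosome) tracks.

    Positions come from the manifest and are sorted; missing values drop
    their positions.  Tracks shorter than ``min_sites`` are skipped with a
    logged warning (hyperparameters are unidentifiable on tiny tracks).
    """
    if matrix.value_scale != "residual":
        raise ValueError(f"expected residual-scale matrix, got {matrix.value_scale!r}")
    ann = manifest.table.set_index("probe_id")
    missing = matrix.probe_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"probes absent from manifest: {missing[:5].tolist()}")
    ann = ann.loc[matrix.probe_ids]
    dup = ann.duplicated(subset=["chrom", "pos"], keep=False)
    if dup.any():
        first = ann[dup].iloc[0]
        raise ValueError(
            f"duplicate (chromosome, position) ({first['chrom']}, {first['pos']}); "
            "deduplicate the manifest before splitting"
        )
    chroms = ann["chrom"].to_numpy()
    poss = ann["pos"].to_numpy(dtype=float)
    tracks: list[ChromosomeTrack] = []
    n_skipped = 0
    for chrom in sorted(np.unique(chroms)):
        sel = chroms == chrom
        order = np.argsort(poss[sel], kind="stable")
        pos_c = poss[sel][order]
        vals_c = matrix.values[sel][order]
        for j, sample in enumerate(matrix.sample_ids):
            obs = np.isfinite(vals_c[:, j])
            if int(obs.sum()) < min_sites:
                n_skipped += 1
                continue
            tracks.append(
                ChromosomeTrack(
                    sample_id=str(sample),
                    chromosome=int(chrom),
                    positions=pos_c[obs],
                    residuals=vals_c[obs, j],
                )
            )
    if n_skipped:
        logger.warning(
            "split_by_chromosome: skipped %d tracks with fewer than %d sites",
            n_skipped,
            min_sites,
        )
    return tracks
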