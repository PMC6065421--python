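"""Expression container, detection calls, normalisation, and probe tracks.

The array reports, for every sample x probe, a raw intensity and a detection
p-value (probability the signal is indistinguishable from background). A
probe is called expressed in a sample when detection p <= 0.05. Probes then
split into two analysis tracks: a quantitative track (expressed in >= 90% of
samples, analysed on normalised log2 intensities) and a binary track
(expressed in some but not all samples, analysed as presence/absence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import AxisMismatchError, ConfigError, ParseError

STAGES_7 = ("M", "EP", "MP", "LP", "ES", "MS", "LS")
DISEASE_LEVELS = ("case", "control", "unknown")

PROBE_COLUMNS = ["probe_id", "gene_symbol", "chromosome", "probe_start", "tss"]


@dataclass
class ExpressionDataset:
    """sample x probe intensities + detection p-values + probe annotation.

    ``probes`` is indexed by probe_id with columns gene_symbol, chromosome,
    probe_start (1-based), tss (1-based).
    """

    sample_ids: list[str]
    probes: pd.DataFrame
    intensity: np.ndarray
    detection_p: np.ndarray

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.detection_p = np.asarray(self.detection_p, dtype=float)
        shape = (len(self.sample_ids), len(self.probes))
        if self.intensity.shape != shape or self.detection_p.shape != shape:
            raise AxisMismatchError(
                f"intensity {self.intensity.shape} / detection {self.detection_p.shape} "
                f"do not match {shape}"
            )
        if not self.probes.index.is_unique:
            raise ParseError("duplicate probe ids")
        if len(self.probes) and (self.probes["probe_start"] < 1).any():
            raise ParseError("probe_start must be 1-based (>= 1)")
        if self.detection_p.size and (
            np.nanmin(self.detection_p) < 0 or np.nanmax(self.detection_p) > 1
        ):
            raise ParseError("detection p-values must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes.index)

    def intensity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intensity, index=self.sample_ids, columns=self.probes.index)

    def detection_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.detection_p, index=self.sample_ids, columns=self.probes.index)

    def subset_probes(self, probe_ids) -> "ExpressionDataset":
        idx = np.array([self.probes.index.get_loc(p) for p in probe_ids])
        return ExpressionDataset(
            sample_ids=list(self.sample_ids),
            probes=self.probes.iloc[idx].copy(),
            intensity=self.intensity[:, idx].copy(),
            detection_p=self.detection_p[:, idx].copy(),
        )


@dataclass
class DetectionCalls:
    """Boolean expressed matrix: expressed[i, j] <=> detection_p[i, j] <= threshold."""

    sample_ids: list[str]
    probe_ids: list[str]
    expressed: np.ndarray
    threshold: float

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.expressed, index=self.sample_ids, columns=self.probe_ids)

    def probe_fraction(self) -> pd.Series:
        """Fraction of samples expressing each probe."""
        return pd.Series(self.expressed.mean(axis=0), index=self.probe_ids)

    def subset_probes(self, probe_ids) -> "DetectionCalls":
        pos = {p: j for j, p in enumerate(self.probe_ids)}
        idx = np.array([pos[p] for p in probe_ids])
        return DetectionCalls(
            sample_ids=list(self.sample_ids),
            probe_ids=list(probe_ids),
            expressed=self.expressed[:, idx].copy(),
            threshold=self.threshold,
        )


@dataclass
class ProbePartition:
    """Three-way probe split: quantitative (expressed in >= high_fraction of
    samples), variable (in >= 1 sample but < high_fraction), excluded (none)."""

    quantitative: list[str]
    variable: list[str]
    excluded: list[str]
    high_fraction: float = 0.90


# ---------------------------------------------------------------- IO


def read_samples(path) -> pd.DataFrame:
    """Read sample metadata TSV (sample_id, stage, disease)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "stage", "disease"}
    if not required.issubset(df.columns):
        raise ParseError(f"sample metadata must have columns {sorted(required)}")
    bad = set(df["stage"]) - set(STAGES_7)
    if bad:
        raise ParseError(f"unknown stage labels: {sorted(bad)}")
    bad = set(df["disease"]) - set(DISEASE_LEVELS)
    if bad:
        raise ParseError(f"unknown disease labels: {sorted(bad)}")
    return df


def _read_matrix(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = df.columns[~df.dtypes.map(pd.api.types.is_numeric_dtype)]
    if len(non_numeric):
        raise ParseError(f"non-numeric cells in {kind} matrix columns {list(non_numeric)}")
    return df


def read_expression(intensity_path, detection_path, probe_annotation_path) -> ExpressionDataset:
    """Read the intensity/detection/annotation TSV trio with axis validation."""
    inten = _read_matrix(intensity_path, "intensity")
    det = _read_matrix(detection_path, "detection")
    probes = pd.read_csv(probe_annotation_path, sep="\t")
    missing = set(PROBE_COLUMNS) - set(probes.columns)
    if missing:
        raise ParseError(f"probe annotation missing columns {sorted(missing)}")
    probes = probes.set_index("probe_id")
    if list(inten.index) != list(det.index):
        raise AxisMismatchError("intensity and detection sample axes differ")
    if list(inten.columns) != list(det.columns):
        raise AxisMismatchError("intensity and detection probe axes differ")
    if list(inten.columns) != list(probes.index):
        raise AxisMismatchError("probe annotation does not match matrix probe axis")
    return ExpressionDataset(
        sample_ids=[str(s) for s in inten.index],
        probes=probes,
        intensity=inten.to_numpy(),
        detection_p=det.to_numpy(),
    )


def write_expression(ds: ExpressionDataset, intensity_path, detection_path, annotation_path) -> None:
    ds.intensity_frame().rename_axis("sample_id").to_csv(intensity_path, sep="\t")
    ds.detection_frame().rename_axis("sample_id").to_csv(detection_path, sep="\t")
    ds.probes.reset_index().to_csv(annotation_path, sep="\t", index=False)


# ---------------------------------------------------------------- operations


def call_detection(ds: ExpressionDataset, threshold: float = 0.05) -> DetectionCalls:
    """Expressed <=> detection p <= threshold (equality goes to expressed)."""
    if not 0.0 < threshold < 1.0:
        raise ConfigError("detection threshold must be in (0, 1)")
    return DetectionCalls(
        sample_ids=list(ds.sample_ids),
        probe_ids=ds.probe_ids,
        expressed=ds.detection_p <= threshold,
        threshold=threshold,
    )


def quantile_normalize_log2(ds: ExpressionDataset) -> ExpressionDataset:
    """Quantile adjustment across individuals, then log2.

    After the quantile step every sample's sorted intensities equal the
    across-sample rank means; ties within a sample receive the average of the
    corresponding rank means. All probes participate (detected or not).
    """
    x = ds.intensity
    order = np.argsort(x, axis=1, kind="stable")
    ranks = np.empty_like(x)
    rank_means = np.sort(x, axis=1).mean(axis=0)
    row_idx = np.arange(x.shape[0])[:, None]
    ranks[row_idx, order] = rank_means[None, :]
    # average rank means over tied intensities within each sample
    out = np.empty_like(ranks)
    for i in range(x.shape[0]):
        vals, inv = np.unique(x[i], return_inverse=True)
        sums = np.bincount(inv, weights=ranks[i])
        counts = np.bincount(inv)
        out[i] = (sums / counts)[inv]
    if (out <= 0).any():
        raise ConfigError("non-positive value after quantile step; cannot log2")
    return ExpressionDataset(
        sample_ids=list(ds.sample_ids),
        probes=ds.probes.copy(),
        intensity=np.log2(out),
        detection_p=ds.detection_p.copy(),
    )


def partition_probes(calls: DetectionCalls, high_fraction: float = 0.90) -> ProbePartition:
    """Split probes by the fraction of samples expressing them."""
    if not calls.sample_ids:
        raise ConfigError("partition requires at least one sample")
    frac = calls.probe_fraction()
    quant = frac.index[frac >= high_fraction]
    excl = frac.index[frac == 0.0]
    var = frac.index[(frac > 0.0) & (frac < high_fraction)]
    return ProbePartition(
        quantitative=list(quant),
        variable=list(var),
        excluded=list(excl),
        high_fraction=high_fraction,
    )


def sample_quality(calls: DetectionCalls) -> pd.Series:
    """Per-sample proportion of ALL probes expressed (the quality covariate)."""
    if not calls.probe_ids:
        raise ConfigError("sample_quality requires at least one probe")
    return pd.Series(calls.expressed.mean(axis=1), index=calls.sample_ids, name="quality")


def attach_quality(samples: pd.DataFrame, calls: DetectionCalls) -> pd.DataFrame:
    """Return sample metadata with the quality covariate column attached."""
    q = sample_quality(calls)
    out = samples.copy()
    out["quality"] = out["sample_id"].map(q).to_numpy()
    return out
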