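"""Cross-sample peak alignment into a feature matrix.

Direct-infusion FT-ICR data carry no retention time, so alignment is purely a
mass-axis problem: peaks from all samples are pooled, sorted by m/z, and the
sorted sequence is cut wherever the gap between consecutive masses exceeds the
ppm tolerance evaluated at that mass (single-linkage binning).  Each resulting
bin becomes one feature whose consensus m/z is the intensity-weighted mean of
its member peaks.

If one sample contributes two peaks to the same bin (an intra-sample
duplicate, possible with sub-tolerance shoulders), only the most intense peak
is kept — ties broken toward the lower mass — and the discard is recorded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .peaklist_io import PeakList

__all__ = ["FeatureMatrix", "align_peaklists", "matrix_stats"]

logger = logging.getLogger(__name__)


@dataclass
class FeatureMatrix:
    """Aligned features x samples intensity table.

    ``values[i, j]`` is the intensity of feature ``i`` in sample ``j`` (0 when
    absent).  ``provenance[i][j]`` is the index of the source peak within the
    sample's peak list, or None.  ``feature_mzs`` are strictly ascending
    consensus masses.
    """

    feature_mzs: np.ndarray            # (n_features,)
    sample_ids: list[str]
    values: np.ndarray                 # (n_features, n_samples)
    provenance: list[list[int | None]] = field(default_factory=list)
    sample_meta: pd.DataFrame | None = None  # indexed by sample_id

    def __post_init__(self) -> None:
        self.feature_mzs = np.asarray(self.feature_mzs, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_mzs), len(self.sample_ids)):
            raise ValueError("values shape inconsistent with mzs/samples")
        if np.any(np.diff(self.feature_mzs) <= 0):
            raise ValueError("feature_mzs must be strictly ascending")
        if np.any(self.values < 0):
            raise ValueError("intensities must be >= 0")

    @property
    def n_features(self) -> int:
        return len(self.feature_mzs)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.sample_ids)
        df.insert(0, "mz", self.feature_mzs)
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def subset_samples(self, sample_ids: list[str]) -> "FeatureMatrix":
        """Column subset (features with all-zero rows are retained)."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[sample_ids]
        return FeatureMatrix(
            feature_mzs=self.feature_mzs.copy(), sample_ids=list(sample_ids),
            values=self.values[:, idx].copy(),
            provenance=[[row[i] for i in idx] for row in self.provenance]
            if self.provenance else [],
            sample_meta=meta)

    def drop_features(self, feature_idx) -> "FeatureMatrix":
        keep = np.ones(self.n_features, dtype=bool)
        keep[list(feature_idx)] = False
        return FeatureMatrix(
            feature_mzs=self.feature_mzs[keep], sample_ids=list(self.sample_ids),
            values=self.values[keep],
            provenance=[r for r, k in zip(self.provenance, keep) if k]
            if self.provenance else [],
            sample_meta=self.sample_meta)


def align_peaklists(peaklists: list[PeakList], tol_ppm: float = 1.0) -> FeatureMatrix:
    """Align peak lists into a :class:`FeatureMatrix` at ``tol_ppm`` tolerance.

    All peaks are pooled and sorted; a new feature starts wherever the gap to
    the previous mass exceeds ``tol_ppm * mean(mz) / 1e6`` (mean of the two
    adjacent masses).  ``tol_ppm = 0`` groups only exactly equal masses.
    Deterministic and independent of input order.
    """
    if not peaklists:
        raise ValueError("align_peaklists requires at least one peak list")
    modes = {pl.mode for pl in peaklists}
    if len(modes) > 1:
        raise ValueError(f"all peak lists must share one ionization mode, got {modes}")
    if tol_ppm < 0:
        raise ValueError("tol_ppm must be >= 0")

    sample_ids = [pl.sample_id for pl in peaklists]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError("duplicate sample_ids in input")

    mzs, intens, samp_idx, peak_idx = [], [], [], []
    for j, pl in enumerate(peaklists):
        for k, p in enumerate(pl.peaks):
            mzs.append(p.mz)
            intens.append(p.intensity)
            samp_idx.append(j)
            peak_idx.append(k)

    n_samples = len(peaklists)
    if not mzs:
        return FeatureMatrix(feature_mzs=np.empty(0), sample_ids=sample_ids,
                             values=np.empty((0, n_samples)), provenance=[],
                             sample_meta=_meta_frame(peaklists))

    mzs = np.asarray(mzs)
    intens = np.asarray(intens)
    samp_idx = np.asarray(samp_idx)
    peak_idx = np.asarray(peak_idx)
    order = np.argsort(mzs, kind="stable")
    mzs, intens = mzs[order], intens[order]
    samp_idx, peak_idx = samp_idx[order], peak_idx[order]

    gaps = np.diff(mzs)
    mids = 0.5 * (mzs[:-1] + mzs[1:])
    if tol_ppm == 0:
        new_bin = gaps > 0
    else:
        new_bin = gaps > tol_ppm * mids / 1e6
    bin_id = np.concatenate([[0], np.cumsum(new_bin)])
    n_bins = bin_id[-1] + 1

    feature_mzs = np.empty(n_bins)
    values = np.zeros((n_bins, n_samples))
    provenance: list[list[int | None]] = [[None] * n_samples for _ in range(n_bins)]
    n_discarded = 0

    start = 0
    for b in range(n_bins):
        end = start
        while end < len(mzs) and bin_id[end] == b:
            end += 1
        m, it = mzs[start:end], intens[start:end]
        sj, pk = samp_idx[start:end], peak_idx[start:end]
        w = it.sum()
        feature_mzs[b] = float(np.average(m, weights=it)) if w > 0 else float(m.mean())
        # best peak per sample: highest intensity, tie broken toward lower mz
        best: dict[int, int] = {}
        for i in range(len(m)):
            j = int(sj[i])
            if j in best:
                n_discarded += 1
                k = best[j]
                if (it[i], -m[i]) > (it[k], -m[k]):
                    logger.info("alignment: sample %s discarded duplicate peak "
                                "m/z %.6f in feature %d", sample_ids[j],
                                float(m[k]), b)
                    best[j] = i
                else:
                    logger.info("alignment: sample %s discarded duplicate peak "
                                "m/z %.6f in feature %d", sample_ids[j],
                                float(m[i]), b)
            else:
                best[j] = i
        for j, i in best.items():
            values[b, j] = it[i]
            provenance[b][j] = int(pk[i])
        start = end

    if n_discarded:
        logger.info("alignment: %d intra-sample duplicate peaks discarded",
                    n_discarded)
    return FeatureMatrix(feature_mzs=feature_mzs, sample_ids=sample_ids,
                         values=values, provenance=provenance,
                         sample_meta=_meta_frame(peaklists))


def _meta_frame(peaklists: list[PeakList]) -> pd.DataFrame:
    return pd.DataFrame(
        {"strain_id": [pl.strain_id for pl in peaklists],
         "fraction": [pl.fraction for pl in peaklists],
         "site": [pl.site for pl in peaklists],
         "age_class": [pl.age_class for pl in peaklists]},
        index=pd.Index([pl.sample_id for pl in peaklists], name="sample_id"))


def matrix_stats(matrix: FeatureMatrix) -> dict:
    """Summary counts: total features and per-sample non-zero feature counts."""
    per_sample = (matrix.values > 0).sum(axis=0)
    return {
        "n_features": matrix.n_features,
        "n_samples": matrix.n_samples,
        "per_sample_features": dict(zip(matrix.sample_ids,
                                        (int(c) for c in per_sample))),
        "min_per_sample": int(per_sample.min()) if matrix.n_samples else 0,
        "max_per_sample": int(per_sample.max()) if matrix.n_samples else 0,
    }
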