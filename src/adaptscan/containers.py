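"""Shared in-memory containers.

Genotypes are stored as alt-allele dosage matrices (samples x markers) with
values in {0, 1, 2} and ``nan`` for missing calls, accompanied by a marker map
(chromosome, 1-based position, ref/alt allele) and a list of sample ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError

MARKER_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt"]


def make_marker_frame(chrom, pos, ref=None, alt=None, marker_id=None) -> pd.DataFrame:
    """Assemble a marker map DataFrame; ids default to ``chrom:pos``."""
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos, dtype=np.int64)
    n = len(pos)
    if ref is None:
        ref = np.full(n, "A", dtype=object)
    if alt is None:
        alt = np.full(n, "T", dtype=object)
    if marker_id is None:
        marker_id = np.array([f"{c}:{p}" for c, p in zip(chrom, pos)], dtype=object)
    frame = pd.DataFrame(
        {"marker_id": marker_id, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt}
    )
    if (frame["pos"] < 1).any():
        raise FormatError("marker positions must be 1-based (>= 1)")
    if frame.duplicated(["chrom", "pos"]).any():
        raise FormatError("duplicate (chromosome, position) in marker map")
    return frame


@dataclass
class GenotypeMatrix:
    """Samples x markers alt-allele dosage matrix with marker map."""

    dosages: np.ndarray
    markers: pd.DataFrame
    sample_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise FormatError("dosage matrix must be 2-D (samples x markers)")
        if self.dosages.shape[1] != len(self.markers):
            raise FormatError(
                f"marker map length {len(self.markers)} does not match "
                f"matrix width {self.dosages.shape[1]}"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i}" for i in range(self.dosages.shape[0])]
        if len(self.sample_ids) != self.dosages.shape[0]:
            raise FormatError("sample id count does not match matrix height")
        with np.errstate(invalid="ignore"):
            ok = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not ok.all():
            bad = self.dosages[~ok].flat[0]
            raise FormatError(f"dosage value {bad!r} outside {{0,1,2,missing}}")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def take_samples(self, index) -> "GenotypeMatrix":
        """Row-subset by positional index, preserving the marker map."""
        index = np.asarray(index)
        return GenotypeMatrix(
            self.dosages[index],
            self.markers,
            [self.sample_ids[i] for i in index],
        )
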