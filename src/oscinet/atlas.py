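"""Region-of-interest atlas: 130 cortical parcels in 8 functional systems.

The pipeline operates on source-reconstructed ROI time series from a
130-region cortical parcellation whose parcels are grouped into eight
functional systems.  :func:`default_atlas` returns a packaged synthetic
stand-in label table (see :mod:`oscinet.atlas_synthetic`); real analyses
can construct an :class:`AtlasSpec` from their own parcellation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas_synthetic import SYNTHETIC_REGION_TABLE

N_ROIS = 130
N_SYSTEMS = 8

SYSTEMS: tuple[str, ...] = (
    "frontoparietal",
    "attention",
    "motor_somatosensory",
    "cinguloopercular",
    "visual",
    "medial_default_mode",
    "ventral_temporal_association",
    "auditory",
)


@dataclass(frozen=True)
class AtlasSpec:
    """An ordered 130-ROI parcellation with hemisphere and system labels.

    Parameters
    ----------
    roi_labels
        Ordered unique ROI names, length 130.
    hemisphere
        Per-ROI hemisphere flag, each ``"L"`` or ``"R"``.
    system
        Per-ROI functional-system assignment; exactly 8 distinct systems
        must be present.
    """

    roi_labels: tuple[str, ...]
    hemisphere: tuple[str, ...]
    system: tuple[str, ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.roi_labels) != N_ROIS:
            raise ValueError(f"atlas must have exactly {N_ROIS} ROIs, got {len(self.roi_labels)}")
        if len(set(self.roi_labels)) != N_ROIS:
            raise ValueError("ROI labels must be unique")
        if len(self.hemisphere) != N_ROIS or len(self.system) != N_ROIS:
            raise ValueError("hemisphere and system must be per-ROI (length 130)")
        if not set(self.hemisphere) <= {"L", "R"}:
            raise ValueError("hemisphere flags must be 'L' or 'R'")
        if len(set(self.system)) != N_SYSTEMS:
            raise ValueError(
                f"expected exactly {N_SYSTEMS} distinct systems, got {len(set(self.system))}"
            )
        object.__setattr__(self, "_index", {lab: i for i, lab in enumerate(self.roi_labels)})

    def __len__(self) -> int:
        return N_ROIS

    def index(self, label: str) -> int:
        """Position of an ROI label in atlas order."""
        return self._index[label]

    def rois_in_system(self, system: str) -> list[str]:
        if system not in SYSTEMS:
            raise KeyError(f"unknown system {system!r}")
        return [lab for lab, sys_ in zip(self.roi_labels, self.system) if sys_ == system]

    def to_frame(self):
        """Atlas as a tidy DataFrame (roi, hemisphere, system)."""
        import pandas as pd

        return pd.DataFrame(
            {"roi": self.roi_labels, "hemisphere": self.hemisphere, "system": self.system}
        )


def default_atlas() -> AtlasSpec:
    """The packaged synthetic 130-ROI atlas (65 regions x 2 hemispheres).

    Deterministic: hemispheres are interleaved (L then R per base region)
    so homologous parcels are adjacent in atlas order.
    """
    labels, hemis, systems = [], [], []
    for base, system in SYNTHETIC_REGION_TABLE:
        for hemi in ("L", "R"):
            labels.append(f"{base}_{hemi}")
            hemis.append(hemi)
            systems.append(system)
    return AtlasSpec(tuple(labels), tuple(hemis), tuple(systems))


def as_roi_indices(atlas: AtlasSpec, rois) -> np.ndarray:
    """Resolve ROI labels or integer positions to atlas indices."""
    out = []
    for r in rois:
        if isinstance(r, (int, np.integer)):
            if not 0 <= r < N_ROIS:
                raise IndexError(f"ROI index {r} out of range")
            out.append(int(r))
        else:
            out.append(atlas.index(r))
    return np.asarray(out, dtype=int)
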