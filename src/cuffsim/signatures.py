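"""Spatial-emphasis (SE) and temporal-emphasis (TE) signature images.

Both signatures are 56 x 100 images of the same tripolar recording — time
on the x-axis, contact on the y-axis, pixel value the recorded voltage —
differing only in how contact rows are grouped:

* SE groups contacts by cuff layer: layer 1's eight contacts (long edge A
  positions 1-4, then edge B positions 1-4), then layer 2, ..., layer 7.
* TE groups contacts by axial column: one cross-sectional contact
  position's seven layers consecutively, for each of the eight positions
  (edge A positions 1-4, then edge B).

TE is therefore a fixed row permutation of SE; the permutation tables are
derived from the electrode layout and are the canonical ordering contract
between dataset generation and classification.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from cuffsim.geometry import ElectrodeLayout
from cuffsim.simulate import Recording


class SignatureError(ValueError):
    """Recording shape incompatible with the electrode layout."""


def se_permutation(layout: ElectrodeLayout) -> np.ndarray:
    """Channel indices in layer-major order (SE row order)."""
    return np.lexsort(
        (layout.within_edge_index, layout.edge_index, layout.layer_index)
    )


def te_permutation(layout: ElectrodeLayout) -> np.ndarray:
    """Channel indices in axial-column-major order (TE row order)."""
    return np.lexsort(
        (layout.layer_index, layout.within_edge_index, layout.edge_index)
    )


def _rows(recording: Recording | np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    data = recording.data if isinstance(recording, Recording) else np.asarray(recording)
    if data.ndim != 2 or data.shape[0] != layout.n_contacts:
        raise SignatureError(
            f"expected ({layout.n_contacts}, T) channels, got {data.shape}"
        )
    return data


def make_se(recording: Recording | np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Spatial-emphasis image: rows grouped layer by layer."""
    return _rows(recording, layout)[se_permutation(layout)]


def make_te(recording: Recording | np.ndarray, layout: ElectrodeLayout) -> np.ndarray:
    """Temporal-emphasis image: rows grouped axial column by axial column."""
    return _rows(recording, layout)[te_permutation(layout)]


@dataclasses.dataclass
class SignaturePair:
    """Paired SE/TE images for one nCAP plus its class label."""

    se: np.ndarray
    te: np.ndarray
    label: int
    se_rows: np.ndarray | None = None  # channel order used for SE rows
    te_rows: np.ndarray | None = None


def make_signature_pair(
    recording: Recording | np.ndarray, layout: ElectrodeLayout, label: int
) -> SignaturePair:
    se_p, te_p = se_permutation(layout), te_permutation(layout)
    rows = _rows(recording, layout)
    return SignaturePair(
        se=rows[se_p], te=rows[te_p], label=label, se_rows=se_p, te_rows=te_p
    )
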