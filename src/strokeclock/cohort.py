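"""Per-patient image intensity ratios and the cohort analysis table.

The timing biomarker for every map type is the ratio of the mean map value
in the ischemic VOI to the mean in the mirrored nonischemic reference VOI,
computed on each map's native units (ms for T2, um^2/ms for ADC, arbitrary
units for the weighted images).  Ratios, the true onset time, and the
within-window label (onset <= 270 min) are assembled into one table per
cohort.

The treatment-window boundary is ambiguous between "within 4.5 hours" and a
strict "< 270 minutes"; the default counts exactly 270 min as within, with a
``strict_boundary`` flag for the alternative reading.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .lesion_voi import VoiPair
from .phantom import WINDOW_MINUTES
from .qmaps import QuantMapSet

__all__ = ["MAP_TYPES", "intensity_ratio", "build_cohort_table", "within_window_label"]

#: map types a cohort table may carry, in column order
MAP_TYPES = ("adc", "dwi", "t2w", "t2", "flair")

COLUMNS = ("patient_id", "onset_min", "label",
           "ratio_adc", "ratio_dwi", "ratio_t2w", "ratio_t2", "ratio_flair",
           "lesion_ml")


def intensity_ratio(volume: np.ndarray, voi: VoiPair) -> float:
    """Mean value in the ischemic VOI divided by the mean in the reference VOI."""
    volume = np.asarray(volume, dtype=float)
    if volume.shape != voi.ischemic.shape:
        raise ValueError("volume and VOI masks must share one grid")
    ref_mean = float(volume[voi.reference].mean())
    if ref_mean == 0.0:
        raise ValueError("reference VOI mean is zero; ratio undefined")
    return float(volume[voi.ischemic].mean()) / ref_mean


def within_window_label(onset_minutes: float, window_min: float = WINDOW_MINUTES,
                        strict_boundary: bool = False) -> int:
    """1 iff the onset time is within the treatment window."""
    if strict_boundary:
        return int(onset_minutes < window_min)
    return int(onset_minutes <= window_min)


def build_cohort_table(patient_ids: Sequence[str],
                       onsets_min: Sequence[float],
                       map_sets: Sequence[QuantMapSet],
                       vois: Sequence[VoiPair],
                       window_min: float = WINDOW_MINUTES,
                       strict_boundary: bool = False) -> pd.DataFrame:
    """Assemble the cohort analysis table, one row per patient.

    Rows are ordered by patient id.  A missing map (e.g. no FLAIR scan) is
    recorded as an absent value, not an error; T2 and ADC ratios are always
    required.
    """
    n = len(patient_ids)
    if not (len(onsets_min) == len(map_sets) == len(vois) == n):
        raise ValueError("one onset, map set and VOI pair per patient required")
    rows = []
    for pid, onset, maps, voi in zip(patient_ids, onsets_min, map_sets, vois):
        row: dict[str, object] = {
            "patient_id": pid,
            "onset_min": float(onset),
            "label": within_window_label(onset, window_min, strict_boundary),
            "lesion_ml": voi.lesion_volume_ml,
        }
        for name in MAP_TYPES:
            vol = maps.map_volume(name)
            row[f"ratio_{name}"] = (np.nan if vol is None
                                    else intensity_ratio(vol, voi))
        rows.append(row)
    table = pd.DataFrame(rows).sort_values("patient_id", kind="stable")
    return table.reset_index(drop=True)[list(COLUMNS)]
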