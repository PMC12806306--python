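"""Survival-target helpers shared by the estimators."""

from __future__ import annotations

import numpy as np


def make_survival_target(time, event) -> np.ndarray:
    """Pack (time, event) into the structured array the estimators accept,
    field-compatible with scikit-survival's convention (event first)."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    y = np.empty(len(time), dtype=[("event", "?"), ("time", "<f8")])
    y["event"] = event.astype(bool)
    y["time"] = time
    return y


def check_survival_y(y) -> tuple[np.ndarray, np.ndarray]:
    """Extract (times, events) from a structured array, a (time, event)
    tuple of vectors, or an (n, 2) array with columns (time, event)."""
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = y.dtype.names
        time_field = next(
            (f for f in names if np.issubdtype(y.dtype[f], np.floating)), None
        )
        event_field = next((f for f in names if f != time_field), None)
        if time_field is None or event_field is None:
            raise ValueError("structured y must carry an event field and a float time field")
        times = np.asarray(y[time_field], dtype=float)
        events = np.asarray(y[event_field]).astype(int)
    elif isinstance(y, (tuple, list)) and len(y) == 2:
        times = np.asarray(y[0], dtype=float)
        events = np.asarray(y[1]).astype(int)
    else:
        arr = np.asarray(y, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError(
                "y must be a structured (event, time) array, a (time, event) "
                "pair of vectors, or an (n, 2) array with columns (time, event)"
            )
        times, events = arr[:, 0], arr[:, 1].astype(int)
    if np.any(times <= 0):
        raise ValueError("survival times must be strictly positive")
    if not np.isin(events, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return times, events
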