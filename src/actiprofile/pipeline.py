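"""End-to-end per-subject processing: epochs -> wear filter -> metrics."""

from __future__ import annotations

import json

import pandas as pd

from .epochs import EpochSeries
from .metrics import compute_profile
from .wear import assess_validity, detect_nonwear, diurnal_weights


def process_subject(series: EpochSeries):
    """Run the wear pipeline for one subject.

    Returns ``(mask, validity_report, weights_or_None)``; weights are
    computed only when the record passes the validity rules.
    """
    mask = detect_nonwear(series)
    report = assess_validity(series, mask)
    weights = diurnal_weights(series, mask) if report.valid else None
    return mask, report, weights


def metrics_table(series_iter, require_valid: bool = True) -> pd.DataFrame:
    """Profile-metrics table, one row per subject with a valid record.

    Subjects failing the validity rules are dropped (or kept, with
    metrics computed on whatever wear exists, if ``require_valid`` is
    False and the record remains balanceable).
    """
    rows = []
    for series in series_iter:
        mask, report, weights = process_subject(series)
        if weights is None:
            if require_valid:
                continue
            from .wear import diurnal_weights as dw

            weights = dw(series, mask)
        profile = compute_profile(series, mask, weights)
        rows.append(profile.to_row())
    return pd.DataFrame(rows)


def band_fraction_table(series_iter) -> pd.DataFrame:
    """Long-format audit table of per-subject band fractions."""
    from .metrics import intensity_distribution

    rows = []
    for series in series_iter:
        mask, report, weights = process_subject(series)
        if weights is None:
            continue
        dist = intensity_distribution(series, mask, weights)
        for i, frac in enumerate(dist.fractions):
            rows.append(
                {
                    "subject_id": series.subject_id,
                    "band": i,
                    "band_low": dist.band_edges[i],
                    "band_high": dist.band_edges[i + 1],
                    "midpoint": dist.midpoints[i],
                    "fraction": frac,
                }
            )
    return pd.DataFrame(rows)


def write_validity_report(series: EpochSeries, path):
    """Emit the per-subject wear/validity JSON report."""
    mask, report, _ = process_subject(series)
    payload = {
        "subject_id": series.subject_id,
        "nonwear_intervals": [
            [str(a), str(b)] for a, b in mask.nonwear_intervals
        ],
        **report.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
    return payload
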