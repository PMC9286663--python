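"""Overlap-consistency assessment between adjacent flightlines.

Adjacent flightlines image a shared ground strip from opposite sides of
their swaths; after a good directional correction, co-located pixels should
agree.  For each overlap pair and band this module fits a simple linear
regression of the later line's values on the earlier line's, and reports

* ``rmse`` - root mean squared residual of that regression,
* ``mad``  - mean absolute deviation of the raw paired differences,
* ``slope`` / ``intercept`` of the regression.

The two conventions are deliberately different so the metrics are not
redundant: a constant offset between lines shows up in MAD but not in the
regression RMSE.  The alternative conventions (``rmse_diff`` on raw
differences, ``mad_resid`` on residuals) are also computed and stored.

Lower RMSE and MAD mean better cross-line consistency.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .brdf import nearest_band
from .errors import DataError

#: Default 10-wavelength assessment subset (nm) spanning the VSWIR range.
DEFAULT_BAND_SUBSET_NM = (480, 560, 660, 850, 975, 1050, 1150, 1240, 1650, 2215)


@dataclass
class OverlapPair:
    """Pixel pairing between two lines sharing a map grid."""

    line_a: str
    line_b: str
    rows_a: np.ndarray
    cols_a: np.ndarray
    rows_b: np.ndarray
    cols_b: np.ndarray

    @property
    def n_pairs(self):
        return self.rows_a.size


def find_overlap(header_a, header_b, line_a="a", line_b="b") -> OverlapPair:
    """Pair pixels whose map coordinates coincide within half a pixel.

    Both headers must share pixel size and grid orientation; the offset
    between upper-left corners may be any real number, and only pixels whose
    centers land within half a pixel of one another are paired.
    """
    ma, mb = header_a.map_info, header_b.map_info
    if not (np.isclose(ma.x_size, mb.x_size) and np.isclose(ma.y_size, mb.y_size)
            and np.isclose(ma.rotation, mb.rotation)):
        raise DataError("overlap requires a shared pixel size and grid orientation")
    # fractional pixel offset of b's origin in a's grid
    off_col = (mb.ulx - ma.ulx) / ma.x_size
    off_row = (ma.uly - mb.uly) / ma.y_size
    empty = OverlapPair(line_a, line_b, *(np.empty(0, dtype=int),) * 4)
    if abs(off_col - round(off_col)) > 0.5 or abs(off_row - round(off_row)) > 0.5:
        return empty  # grids misaligned beyond half a pixel: nothing pairs
    dc, dr = int(round(off_col)), int(round(off_row))
    # b pixel (r, c) sits at a pixel (r + dr, c + dc)
    col_lo = max(0, dc)
    col_hi = min(header_a.n_cols, header_b.n_cols + dc)
    row_lo = max(0, dr)
    row_hi = min(header_a.n_rows, header_b.n_rows + dr)
    if col_lo >= col_hi or row_lo >= row_hi:
        return empty
    rows_a, cols_a = np.mgrid[row_lo:row_hi, col_lo:col_hi]
    rows_a, cols_a = rows_a.ravel(), cols_a.ravel()
    return OverlapPair(line_a, line_b, rows_a, cols_a,
                       rows_a - dr, cols_a - dc)


@dataclass
class BandStatistics:
    band_index: int
    wavelength: float
    n: int
    rmse: float  # regression residual RMSE
    mad: float  # mean |paired difference|
    slope: float
    intercept: float
    rmse_diff: float  # RMSE of paired differences
    mad_resid: float  # mean |regression residual|
    degenerate: bool = False  # zero predictor variance; regression undefined


@dataclass
class AssessmentReport:
    """Per-band overlap statistics for one pair, or group-averaged."""

    line_a: str
    line_b: str
    bands: list = field(default_factory=list)  # list[BandStatistics]

    def as_rows(self):
        for b in self.bands:
            yield {
                "line_a": self.line_a, "line_b": self.line_b,
                "band_index": b.band_index, "wavelength": b.wavelength,
                "n_pairs": b.n, "rmse": b.rmse, "mad": b.mad,
                "slope": b.slope, "intercept": b.intercept,
                "rmse_diff": b.rmse_diff, "mad_resid": b.mad_resid,
                "degenerate": int(b.degenerate),
            }


def overlap_statistics(cube_a, cube_b, pair: OverlapPair,
                       band_indices=None) -> AssessmentReport:
    """Per-band overlap statistics; line a is the predictor (convention:
    the earlier-acquired line)."""
    if pair.n_pairs < 2:
        raise DataError("overlap pair has fewer than 2 pixel pairs")
    if cube_a.header.n_bands != cube_b.header.n_bands:
        raise DataError("cubes do not share a band set")
    ok = (cube_a.valid_mask[pair.rows_a, pair.cols_a]
          & cube_b.valid_mask[pair.rows_b, pair.cols_b])
    if ok.sum() < 2:
        raise DataError("fewer than 2 valid co-located pixel pairs")
    ra, ca = pair.rows_a[ok], pair.cols_a[ok]
    rb, cb = pair.rows_b[ok], pair.cols_b[ok]
    if band_indices is None:
        band_indices = range(cube_a.header.n_bands)
    wl = cube_a.header.wavelengths
    report = AssessmentReport(pair.line_a, pair.line_b)
    for band in band_indices:
        x = cube_a.values[band, ra, ca]
        y = cube_b.values[band, rb, cb]
        diff = y - x
        mad = float(np.mean(np.abs(diff)))
        rmse_diff = float(np.sqrt(np.mean(diff**2)))
        if np.ptp(x) == 0.0:
            report.bands.append(BandStatistics(
                band_index=int(band),
                wavelength=float(wl[band]) if wl is not None else np.nan,
                n=int(x.size), rmse=rmse_diff, mad=mad,
                slope=np.nan, intercept=np.nan,
                rmse_diff=rmse_diff, mad_resid=mad, degenerate=True,
            ))
            continue
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        report.bands.append(BandStatistics(
            band_index=int(band),
            wavelength=float(wl[band]) if wl is not None else np.nan,
            n=int(x.size),
            rmse=float(np.sqrt(np.mean(resid**2))),
            mad=mad,
            slope=float(slope), intercept=float(intercept),
            rmse_diff=rmse_diff,
            mad_resid=float(np.mean(np.abs(resid))),
        ))
    return report


def band_subset(wavelengths, targets=DEFAULT_BAND_SUBSET_NM, tol_nm=20.0):
    """Nearest-band index per target wavelength (duplicates allowed)."""
    import logging

    indices = [nearest_band(wavelengths, t, tol_nm) for t in targets]
    if len(set(indices)) < len(indices):
        logging.getLogger(__name__).warning(
            "band subset contains duplicate band indices: %s", indices)
    return indices


def group_average(reports) -> AssessmentReport:
    """Unweighted mean of each statistic across overlap pairs, per band."""
    reports = [r for r in reports if r.bands]
    if not reports:
        raise DataError("no non-empty overlap reports to average")
    n_bands = len(reports[0].bands)
    if any(len(r.bands) != n_bands for r in reports):
        raise DataError("reports cover different band sets")
    out = AssessmentReport("group", "average")
    for i in range(n_bands):
        per = [r.bands[i] for r in reports]
        mean = lambda attr: float(np.nanmean([getattr(b, attr) for b in per]))
        out.bands.append(BandStatistics(
            band_index=per[0].band_index, wavelength=per[0].wavelength,
            n=int(sum(b.n for b in per)),
            rmse=mean("rmse"), mad=mean("mad"),
            slope=mean("slope"), intercept=mean("intercept"),
            rmse_diff=mean("rmse_diff"), mad_resid=mean("mad_resid"),
            degenerate=any(b.degenerate for b in per),
        ))
    return out


def write_reports(reports, csv_path=None, json_path=None, group=None):
    """Emit per-pair rows plus group-average rows as CSV and/or JSON."""
    rows = [row for rep in reports for row in rep.as_rows()]
    if group is not None:
        rows += list(group.as_rows())
    if csv_path:
        with open(csv_path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)
    if json_path:
        with open(json_path, "w") as fh:
            json.dump(rows, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return rows
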