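"""Independent brute-force reference implementations.

Everything here is written as plain double loops over cells and records,
deliberately sharing no code with the package, so tests can compare the
vectorised pipeline against a transparent reference.
"""

from __future__ import annotations

import math

import numpy as np

AUTHALIC_R = 6_371_007.2


def cell_area_loop(n_rows, n_cols, cell_size, origin_lat):
    """Per-cell area in hectares, one trigonometric evaluation per row."""
    out = np.zeros((n_rows, n_cols))
    dlam = math.radians(cell_size)
    for r in range(n_rows):
        top = math.radians(origin_lat - r * cell_size)
        bot = math.radians(origin_lat - (r + 1) * cell_size)
        a = AUTHALIC_R**2 * dlam * (math.sin(top) - math.sin(bot)) / 1e4
        for c in range(n_cols):
            out[r, c] = a
    return out


def production_loop(ha, yld, water_pct, dry):
    """P = yield * HA, optionally * (1 - w/100), cell by cell."""
    n_rows, n_cols = ha.shape
    out = np.zeros((n_rows, n_cols))
    f = (1.0 - water_pct / 100.0) if dry else 1.0
    for r in range(n_rows):
        for c in range(n_cols):
            out[r, c] = yld[r, c] * ha[r, c] * f
    return out


def country_metrics_loop(ha, yld, sr, water_pct, zone_cells, dry=True, zero_tol=1e-9):
    """Country totals and production-weighted BP by explicit summation.

    ``zone_cells`` maps country id -> list of (row, col, coverage).
    Returns dict country -> (production_total, asr_total, bp_mean, bp_prod).
    """
    out = {}
    for cid, cells in zone_cells.items():
        p_tot = 0.0
        asr_tot = 0.0
        num = 0.0
        den = 0.0
        for r, c, cov in cells:
            p = production_loop(
                ha[r : r + 1, c : c + 1], yld[r : r + 1, c : c + 1], water_pct, dry
            )[0, 0]
            asr = ha[r, c] * sr[r, c]
            p_tot += cov * p
            asr_tot += cov * asr
            if p > zero_tol:
                bp_cell = asr / p
                num += cov * p * bp_cell
                den += cov * p
        bp_mean = num / den if den > 0 else float("nan")
        bp_prod = bp_mean * p_tot if den > 0 else float("nan")
        out[cid] = (p_tot, asr_tot, bp_mean, bp_prod)
    return out


def bp_cons_loop(supply, focal_bp, import_flows):
    """Direct evaluation: C_dom * BP_fc + sum_i T_i * BP_i.

    ``import_flows`` is a list of (tonnes, origin_bp) pairs; origins with
    BP None are skipped (unattributed).
    """
    total = supply * focal_bp if supply > 0 else 0.0
    for tonnes, origin_bp in import_flows:
        if origin_bp is not None:
            total += tonnes * origin_bp
    return total


def bilinear_point(src_vals, src_lats, src_lons, lat, lon):
    """Bilinear interpolation of one point from centre coordinates."""
    # src_lats descending
    fy = (src_lats[0] - lat) / (src_lats[0] - src_lats[1])
    fx = (lon - src_lons[0]) / (src_lons[1] - src_lons[0])
    y0 = min(max(int(math.floor(fy)), 0), len(src_lats) - 2)
    x0 = min(max(int(math.floor(fx)), 0), len(src_lons) - 2)
    ty = min(max(fy - y0, 0.0), 1.0)
    tx = min(max(fx - x0, 0.0), 1.0)
    return (
        src_vals[y0, x0] * (1 - ty) * (1 - tx)
        + src_vals[y0, x0 + 1] * (1 - ty) * tx
        + src_vals[y0 + 1, x0] * ty * (1 - tx)
        + src_vals[y0 + 1, x0 + 1] * ty * tx
    )
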