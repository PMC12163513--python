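import numpy as np
import pandas as pd
import pytest

from morphohet.types import LabelMap, SectionProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)


def make_label_map(pixels, section_id="S1", tumor_id="T1", role="central"):
    return LabelMap(pixels=np.asarray(pixels, dtype=np.int64),
                    section_id=section_id, tumor_id=tumor_id, role=role)


def make_profile(props, section_id="S1", tumor_id="T1", role="central",
                 retained=1000):
    props = np.asarray(props, dtype=float)
    return SectionProfile(section_id=section_id, tumor_id=tumor_id, role=role,
                          proportions=props, tumor_area_px=retained,
                          retained_area_px=retained if props.sum() > 0 else 0)


@pytest.fixture
def clinical_df():
    """A minimal well-formed clinical table (3 tumors)."""
    return pd.DataFrame(
        {
            "tumor_id": ["T1", "T2", "T3"],
            "age": [62, 71, 55],
            "gender": ["M", "F", "M"],
            "t_stage": ["T2", "T3", "T4"],
            "n_stage": ["N0", "N1", "N2"],
            "m_stage": ["M0", "M0", "M1"],
            "ajcc_stage": ["I", "III", "IV"],
            "grade": [1, 2, 3],
            "site": ["right", "left", "rectum"],
            "msi": ["MSS", "MSI", "MSS"],
            "os_time": [60.0, 34.5, 12.0],
            "os_event": [0, 1, 1],
            "rfs_time": [60.0, 20.0, 8.0],
            "rfs_event": [0, 1, 1],
        }
    )


# --- independent oracles -------------------------------------------------

def flood_fill_components(mask, connectivity=8):
    """Brute-force flood-fill component count of a boolean mask."""
    mask = np.asarray(mask, dtype=bool)
    seen = np.zeros_like(mask)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and not seen[r0, c0]:
                count += 1
                stack = [(r0, c0)]
                seen[r0, c0] = True
                while stack:
                    r, c = stack.pop()
                    for dr, dc in nbrs:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] and not seen[rr, cc]:
                            seen[rr, cc] = True
                            stack.append((rr, cc))
    return count


def product_limit(times, events):
    """Hand product-limit estimator: list of (event_time, survival)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    out = []
    for t in np.unique(times[events == 1]):
        n_at_risk = np.sum(times >= t)
        d = np.sum((times == t) & (events == 1))
        s *= 1 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oe(times, events, group1_mask):
    """Hand observed-minus-expected two-group log-rank chi-square."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    g1 = np.asarray(group1_mask, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & g1).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & g1).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return 0.0 if var == 0 else o_minus_e**2 / var


def bh_stepup(p_values):
    """Hand Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        adj[i] = running
    return adj
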