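"""Independent explicit-loop reference implementations used as test oracles.

These deliberately avoid numpy vectorisation and any code path shared with
the package: plain Python loops over nested lists, ``math`` and
``statistics`` only.
"""

import math
import statistics


def size_factors_loops(counts_df):
    """Median-of-ratios with explicit loops: {sample: factor}."""
    genes = list(counts_df.index)
    samples = list(counts_df.columns)
    table = {g: {s: float(counts_df.loc[g, s]) for s in samples} for g in genes}
    reference = [g for g in genes if all(table[g][s] > 0 for s in samples)]
    geo = {}
    for g in reference:
        geo[g] = math.exp(sum(math.log(table[g][s]) for s in samples) / len(samples))
    return {
        s: statistics.median(table[g][s] / geo[g] for g in reference) for s in samples
    }


def _rows(tc_df):
    times = [float(t) for t in tc_df.columns]
    rows = {g: [float(v) for v in tc_df.loc[g]] for g in tc_df.index}
    return times, rows


def changing_genes_loops(tc_df, min_count=100.0, min_abs_l2fc=1.0, pc=1.0):
    times, rows = _rows(tc_df)
    i0 = times.index(0.0)
    out = set()
    for g, vals in rows.items():
        if max(vals) <= min_count:
            continue
        v0 = vals[i0]
        for i, v in enumerate(vals):
            if i == i0:
                continue
            if abs(math.log2((v + pc) / (v0 + pc))) > min_abs_l2fc:
                out.add(g)
                break
    return out


def aggregation_panel_loops(dev_df, fold=2.0):
    times, rows = _rows(dev_df)
    out = set()
    for g, vals in rows.items():
        at = {t: v for t, v in zip(times, vals)}
        mid = (at[4.0] + at[6.0] + at[8.0]) / 3
        initial = (at[0.0] + at[2.0]) / 2
        mound = (at[10.0] + at[12.0] + at[14.0]) / 3
        if mid > fold * initial and mid > fold * mound:
            out.add(g)
    return out


def early_induced_loops(tc_df, horizon=2.0, min_rel=0.5, pc=1.0):
    times, rows = _rows(tc_df)
    i0 = times.index(0.0)
    out = set()
    for g, vals in rows.items():
        best_i = 0
        for i in range(1, len(vals)):
            if vals[i] > vals[best_i]:
                best_i = i  # strict >, so ties keep the earliest timepoint
        if times[best_i] > horizon:
            continue
        if (vals[best_i] + pc) / (vals[i0] + pc) > 1.0 + min_rel:
            out.add(g)
    return out


def transient_induction_loops(tc_df, fold=2.0, pc=1.0):
    times, rows = _rows(tc_df)
    out = set()
    for g, vals in rows.items():
        v0 = vals[0]
        peak = any((v + pc) / (v0 + pc) > fold for v in vals[1:-1])
        returns = (vals[-1] + pc) / (v0 + pc) < fold
        if peak and returns:
            out.add(g)
    return out


def rolling_mean_loops(mid_times, speeds, window_min):
    half = window_min / 60.0 / 2.0
    out = []
    for t in mid_times:
        vals = [s for tm, s in zip(mid_times, speeds) if abs(tm - t) <= half + 1e-12]
        out.append(sum(vals) / len(vals))
    return out


def chi2_2x2_closed_form(a, b, c, d):
    n = a + b + c + d
    return n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))


def fate_marker_loops(table_df, min_abs_l2fc=1.0, max_fdr=0.1, min_max_count=100.0):
    prestalk, prespore = set(), set()
    for g in table_df.index:
        l2fc = float(table_df.loc[g, "log2fc"])
        q = float(table_df.loc[g, "q"])
        mx = float(table_df.loc[g, "max_count"])
        if q < max_fdr and mx > min_max_count:
            if l2fc > min_abs_l2fc:
                prestalk.add(g)
            elif l2fc < -min_abs_l2fc:
                prespore.add(g)
    return prestalk, prespore
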