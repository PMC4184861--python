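"""Naive day-by-day loop implementations of every onset rule.

Pure Python, no NumPy vectorization and no reuse of the package's
kernels: these serve as independent oracles for equivalence tests.
"""

import math

N_PREFIX = 61


def naive_gdd(tmean_year, t_base, gdd_crit, t0=1):
    acc = 0.0
    for i, t in enumerate(tmean_year):
        doy = i + 1
        if doy < t0:
            continue
        acc += max(t - t_base, 0.0)
        if acc >= gdd_crit:
            return doy
    return None


def naive_gdd_series(tmean_year, t_base, t0=1):
    out, acc = [], 0.0
    for i, t in enumerate(tmean_year):
        if i + 1 >= t0:
            acc += max(t - t_base, 0.0)
        out.append(acc)
    return out


def naive_ngd(tmean_year, t_base, ngd_crit, t0=1):
    count = 0
    for i, t in enumerate(tmean_year):
        doy = i + 1
        if doy < t0:
            continue
        if t > t_base:
            count += 1
        if count >= ngd_crit:
            return doy
    return None


def naive_soil(tmean, window):
    out = []
    for i in range(len(tmean)):
        lo = max(0, i - window + 1)
        win = tmean[lo : i + 1]
        out.append(sum(win) / len(win))
    return out


def naive_day_length(lat, doy):
    decl = math.radians(-23.44) * math.cos(2 * math.pi * (doy + 10) / 365.0)
    cosw = -math.tan(math.radians(lat)) * math.tan(decl)
    cosw = max(-1.0, min(1.0, cosw))
    return math.acos(cosw) / math.pi * 86400.0


def naive_bbgc_woody(tmean_full, lat, t_base, a, b, t_avg, gate_s=39300.0, offset=15, window=11):
    soil = naive_soil(list(tmean_full), window)[N_PREFIX:]
    crit = math.exp(a + b * t_avg)
    acc = 0.0
    for i, s in enumerate(soil):
        acc += max(s - t_base, 0.0)
        if acc >= crit and naive_day_length(lat, i + 1) > gate_s:
            return max(i + 1 - offset, 1)
    return None


def naive_bbgc_grass(
    tmean_full, precip_full, t_base, c, d, k, t_avg, ann_precip, offset=15, window=11
):
    soil = naive_soil(list(tmean_full), window)[N_PREFIX:]
    crit_t = c * max(t_avg, 0.0) + d
    crit_p = k * ann_precip
    acc_t = acc_p = 0.0
    for i in range(365):
        acc_t += max(soil[i] - t_base, 0.0)
        acc_p += precip_full[N_PREFIX + i]
        if acc_t >= crit_t and acc_p >= crit_p:
            return max(i + 1 - offset, 1)
    return None


def naive_ncd_gdd(tmean_full, t_chill, t_base, g, h, w):
    ncd = sum(1 for i in range(N_PREFIX) if tmean_full[i] < t_chill)
    gdd = 0.0
    for i in range(365):
        t = tmean_full[N_PREFIX + i]
        if t < t_chill:
            ncd += 1
        gdd += max(t - t_base, 0.0)
        if gdd >= g + h * math.exp(w * ncd):
            return i + 1
    return None
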