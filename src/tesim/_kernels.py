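"""Compiled inner loops for the generation step and population scans.

The population is passed as flat arrays: ``pos`` holds all haplotypes back to
back and ``off`` (length ``2N+1``) delimits them; haplotypes ``2i`` and
``2i+1`` belong to individual ``i``.  A parallel ``codes`` array caches the
site class of every insertion (0=cluster, 1=trigger, 2=paramutable,
3=neutral) so that per-generation counting is a plain tally; codes travel
with the positions through meiosis and only freshly transposed copies are
classified.

All randomness inside the kernels uses numba's own Mersenne–Twister state,
seeded explicitly per call, so a run is fully reproducible from its seed
sequence.  The kernels implement exactly the model of
:mod:`tesim.reproduction`: Poisson crossovers with uniform positions and free
assortment, transposition after recombination with
``lambda = u_eff * n_parent / 2`` and within-gamete collision rejection,
fecundity-weighted parent sampling, and maternal-only transmission of the
piRNA status.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Site-class counting
# ---------------------------------------------------------------------------


@njit(cache=True)
def count_codes(codes, off):
    """Tally cached class codes per individual.

    Returns (n_total, n_cluster, n_para, n_trigger) int64 arrays of length N.
    """
    n = (len(off) - 1) // 2
    n_tot = np.zeros(n, np.int64)
    n_clu = np.zeros(n, np.int64)
    n_par = np.zeros(n, np.int64)
    n_tri = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(off[2 * i], off[2 * i + 2]):
            c = codes[j]
            n_tot[i] += 1
            if c == 0:
                n_clu[i] += 1
            elif c == 1:
                n_tri[i] += 1
            elif c == 2:
                n_par[i] += 1
    return n_tot, n_clu, n_par, n_tri


@njit(cache=True, inline="always")
def _classify_one(p, chrom_ends, cluster_ends, pp, pc, para_all, tp, tc):
    c = 0
    while p >= chrom_ends[c]:
        c += 1
    if p < cluster_ends[c]:
        return 0
    if tc > 0 and p % tp >= tp - tc:
        return 1
    if para_all or (pc > 0 and p % pp < pc):
        return 2
    return 3


@njit(cache=True)
def classify_codes(pos, chrom_ends, cluster_ends, pp, pc, para_all, tp, tc):
    """Class code for every position (used to (re)build the codes cache)."""
    out = np.empty(pos.size, np.uint8)
    for j in range(pos.size):
        out[j] = _classify_one(pos[j], chrom_ends, cluster_ends, pp, pc, para_all, tp, tc)
    return out


# ---------------------------------------------------------------------------
# Fixed insertions (present on every haplotype)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _intersect_sorted(a, b):
    out = np.empty(min(a.size, b.size), np.int64)
    i = 0
    j = 0
    k = 0
    while i < a.size and j < b.size:
        if a[i] == b[j]:
            out[k] = a[i]
            k += 1
            i += 1
            j += 1
        elif a[i] < b[j]:
            i += 1
        else:
            j += 1
    return out[:k]


@njit(cache=True)
def fixed_positions_flat(pos, off):
    """Positions carried by all haplotypes (progressive sorted intersection)."""
    nhap = len(off) - 1
    cand = pos[off[0] : off[1]].copy()
    for h in range(1, nhap):
        if cand.size == 0:
            break
        cand = _intersect_sorted(cand, pos[off[h] : off[h + 1]])
    return cand


# ---------------------------------------------------------------------------
# Generation step
# ---------------------------------------------------------------------------


@njit(cache=True)
def seed_kernel_rng(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _bisect_left(arr, lo, hi, value):
    while lo < hi:
        mid = (lo + hi) // 2
        if arr[mid] < value:
            lo = mid + 1
        else:
            hi = mid
    return lo


@njit(cache=True)
def _gamete_into(
    out,
    out_codes,
    wpos,
    pos,
    codes,
    off,
    h1,
    h2,
    chrom_bounds,
    xover_mean,
    n_transp,
    g,
    chrom_ends,
    cluster_ends,
    pp,
    pc,
    para_all,
    tp,
    tc,
):
    """Write one recombined+transposed gamete (positions and class codes)
    into ``out``/``out_codes`` starting at ``wpos``; returns the new pointer.

    ``h1``/``h2`` are the parent's haplotype indices; ``n_transp`` the
    pre-drawn number of transposition attempts.
    """
    start = wpos
    p1, e1 = off[h1], off[h1 + 1]
    p2, e2 = off[h2], off[h2 + 1]
    n_chrom = xover_mean.size
    bp = np.empty(32, np.int64)
    for c in range(n_chrom):
        cs = chrom_bounds[c]
        ce = chrom_bounds[c + 1]
        if (p1 == e1 or pos[p1] >= ce) and (p2 == e2 or pos[p2] >= ce):
            continue  # chromosome empty on both haplotypes: gamete part empty
        k = 0
        if xover_mean[c] > 0.0:
            k = np.random.poisson(xover_mean[c])
        if k > bp.size:
            bp = np.empty(k, np.int64)
        for t in range(k):  # insertion sort; k is almost always 0-3
            v = cs + np.random.randint(0, ce - cs)
            w = t
            while w > 0 and bp[w - 1] > v:
                bp[w] = bp[w - 1]
                w -= 1
            bp[w] = v
        cur = 0 if np.random.random() < 0.5 else 1
        for t in range(k + 1):
            seg_end = bp[t] if t < k else ce
            i1 = _bisect_left(pos, p1, e1, seg_end)
            i2 = _bisect_left(pos, p2, e2, seg_end)
            if cur == 0:
                seg = i1 - p1
                out[wpos : wpos + seg] = pos[p1:i1]
                out_codes[wpos : wpos + seg] = codes[p1:i1]
                wpos += seg
            else:
                seg = i2 - p2
                out[wpos : wpos + seg] = pos[p2:i2]
                out_codes[wpos : wpos + seg] = codes[p2:i2]
                wpos += seg
            p1 = i1
            p2 = i2
            cur = 1 - cur
    # transposition into the finished gamete; collide only within this gamete
    for _ in range(n_transp):
        cand = np.random.randint(0, g)
        lo = _bisect_left(out, start, wpos, cand)
        if lo < wpos and out[lo] == cand:
            continue  # occupied site: insertion ignored
        for j in range(wpos, lo, -1):
            out[j] = out[j - 1]
            out_codes[j] = out_codes[j - 1]
        out[lo] = cand
        out_codes[lo] = _classify_one(cand, chrom_ends, cluster_ends, pp, pc, para_all, tp, tc)
        wpos += 1
    return wpos


@njit(cache=True)
def step_generation_flat(
    pos,
    codes,
    off,
    sex,
    producer,
    w,
    n_tot,
    chrom_bounds,
    xover_mean,
    u,
    g,
    chrom_ends,
    cluster_ends,
    pp,
    pc,
    para_all,
    tp,
    tc,
):
    """Produce the next generation (N offspring) from flat parent arrays.

    ``producer``/``w``/``n_tot`` are the parents' piRNA-producer flags,
    fitnesses and diploid copy numbers.  Returns ``(new_pos, new_codes,
    new_off, new_sex, new_m, extinct)``; on extinction the arrays are empty
    placeholders.
    """
    n = sex.size
    # fecundity-weighted, sex-restricted parent lottery
    n_f = 0
    n_m = 0
    for i in range(n):
        if sex[i] == 0:
            n_f += 1
        else:
            n_m += 1
    fem = np.empty(n_f, np.int64)
    mal = np.empty(n_m, np.int64)
    fem_cum = np.empty(n_f, np.float64)
    mal_cum = np.empty(n_m, np.float64)
    fi = 0
    mi = 0
    fs = 0.0
    ms = 0.0
    for i in range(n):
        if sex[i] == 0:
            fs += w[i]
            fem[fi] = i
            fem_cum[fi] = fs
            fi += 1
        else:
            ms += w[i]
            mal[mi] = i
            mal_cum[mi] = ms
            mi += 1
    empty_i = np.empty(0, np.int64)
    empty_c = np.empty(0, np.uint8)
    if n_f == 0 or n_m == 0 or fs <= 0.0 or ms <= 0.0:
        return empty_i, empty_c, empty_i, empty_c, empty_c, True

    cap = pos.size + 16 * n + 1024
    out = np.empty(cap, np.int64)
    out_codes = np.empty(cap, np.uint8)
    new_off = np.empty(2 * n + 1, np.int64)
    new_off[0] = 0
    new_sex = np.empty(n, np.uint8)
    new_m = np.empty(n, np.uint8)
    wpos = 0
    for child in range(n):
        r = np.random.random() * fs
        k = _bisect_cum(fem_cum, r)
        mother = fem[k]
        r = np.random.random() * ms
        k = _bisect_cum(mal_cum, r)
        father = mal[k]

        for slot in range(2):
            parent = mother if slot == 0 else father
            lam_t = 0.0 if producer[parent] == 1 else u * n_tot[parent] / 2.0
            k_t = np.random.poisson(lam_t) if lam_t > 0.0 else 0
            need = off[2 * parent + 2] - off[2 * parent] + k_t
            if wpos + need > cap:
                cap = max(2 * cap, wpos + need + 1024)
                grown = np.empty(cap, np.int64)
                grown[:wpos] = out[:wpos]
                out = grown
                grown_c = np.empty(cap, np.uint8)
                grown_c[:wpos] = out_codes[:wpos]
                out_codes = grown_c
            wpos = _gamete_into(
                out,
                out_codes,
                wpos,
                pos,
                codes,
                off,
                2 * parent,
                2 * parent + 1,
                chrom_bounds,
                xover_mean,
                k_t,
                g,
                chrom_ends,
                cluster_ends,
                pp,
                pc,
                para_all,
                tp,
                tc,
            )
            new_off[2 * child + 1 + slot] = wpos
        new_sex[child] = 0 if np.random.random() < 0.5 else 1
        new_m[child] = producer[mother]
    # views into the buffer; callers treat them as immutable
    return out[:wpos], out_codes[:wpos], new_off, new_sex, new_m, False


@njit(cache=True, inline="always")
def _bisect_cum(cum, r):
    """First index whose cumulative weight exceeds r (zero-weight entries
    can never be selected)."""
    lo = 0
    hi = cum.size
    while lo < hi:
        mid = (lo + hi) // 2
        if cum[mid] <= r:
            lo = mid + 1
        else:
            hi = mid
    if lo >= cum.size:
        lo = cum.size - 1
    return lo


# ---------------------------------------------------------------------------
# Purge insertions inside removed cluster regions
# ---------------------------------------------------------------------------


@njit(cache=True)
def purge_regions_flat(pos, off, region_starts, region_ends):
    """Drop every position falling in any ``[start, end)`` region."""
    keep = np.ones(pos.size, np.uint8)
    for j in range(pos.size):
        p = pos[j]
        for r in range(region_starts.size):
            if region_starts[r] <= p < region_ends[r]:
                keep[j] = 0
                break
    new_pos = np.empty(pos.size, np.int64)
    new_off = np.empty(off.size, np.int64)
    new_off[0] = 0
    k = 0
    for h in range(off.size - 1):
        for j in range(off[h], off[h + 1]):
            if keep[j] == 1:
                new_pos[k] = pos[j]
                k += 1
        new_off[h + 1] = k
    return new_pos[:k].copy(), new_off
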