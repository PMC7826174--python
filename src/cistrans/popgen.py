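"""Per-site and windowed divergence statistics and fixation calls.

Fst uses the Weir & Cockerham (1984) theta-hat estimator computed from the
a (among-population), b (among-individual-within-population) and c
(within-individual) variance components, matching the vcftools
``--weir-fst-pop`` convention: per-site theta = a/(a+b+c), window theta =
sum(a)/sum(a+b+c) over analyzed sites (ratio of sums).  Negative estimates
are reported as-is, never clamped.  Dxy is the mean per-site between-
population diversity p1(1-p2) + p2(1-p1) over analyzed variant sites (the
variant-only denominator convention; the absolute threshold is therefore
convention-dependent and exposed in :class:`~cistrans.config.FilterConfig`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .formats_io import (GenotypeMatrix, StructuralVariant, SVCallSet,
                         HET, HOM_ALT, HOM_REF, MISSING)

logger = logging.getLogger(__name__)


@dataclass
class SiteDivergence:
    scaffold: str
    position: int
    fst: float  # may be negative; NaN when undefined
    p1: float  # alt-allele frequency, population 1 (over called genotypes)
    p2: float
    is_fixed: bool


@dataclass
class DivergenceWindow:
    scaffold: str
    start: int
    end: int
    n_sites: int
    fst_window: float
    dxy: float


# ---------------------------------------------------------------------------
# Weir & Cockerham components


def wc_components(genotypes: np.ndarray, cols1: np.ndarray,
                  cols2: np.ndarray):
    """W&C (1984) variance components a, b, c for each site (vectorized).

    ``genotypes`` is (n_sites, n_samples) coded int8; ``cols1``/``cols2`` are
    the column indices of the two populations.  Sites where either population
    has fewer than 2 called genotypes yield NaN components.

    Returns (a, b, c, p1, p2, n1, n2) arrays.
    """
    g1 = genotypes[:, cols1]
    g2 = genotypes[:, cols2]
    out = []
    for g in (g1, g2):
        called = g != MISSING
        n = called.sum(axis=1).astype(float)  # individuals called
        alt = ((g == HET).sum(axis=1) + 2 * (g == HOM_ALT).sum(axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            p = alt / (2 * n)
            h = (g == HET).sum(axis=1) / n  # observed heterozygote frequency
        out.append((n, p, h))
    (n1, p1, h1), (n2, p2, h2) = out

    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r
            - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    bad = (n1 < 2) | (n2 < 2)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c, p1, p2, n1, n2


def _fixed_mask(genotypes: np.ndarray, cols1, cols2) -> np.ndarray:
    """Fixed difference: all called genotypes homozygous, opposite alleles."""
    g1 = genotypes[:, cols1]
    g2 = genotypes[:, cols2]

    def pop_state(g):
        called = g != MISSING
        n = called.sum(axis=1)
        all_ref = ((g == HOM_REF) | ~called).all(axis=1) & (n > 0)
        all_alt = ((g == HOM_ALT) | ~called).all(axis=1) & (n > 0)
        return all_ref, all_alt

    ref1, alt1 = pop_state(g1)
    ref2, alt2 = pop_state(g2)
    return (ref1 & alt2) | (alt1 & ref2)


def wc_fst_site(site, populations=None, *, matrix: GenotypeMatrix = None,
                index: int = None, cols1=None, cols2=None) -> SiteDivergence:
    """Per-site W&C theta-hat for a single :class:`VariantSite`.

    Either pass ``site`` together with ``populations`` (a sequence of labels
    aligned with ``site.genotypes``), or a ``matrix``/``index`` pair.
    """
    if matrix is not None:
        site = matrix.site(index)
        pops = sorted(set(matrix.populations.values()))
        cols1 = matrix.pop_columns(pops[0])
        cols2 = matrix.pop_columns(pops[1])
        g = matrix.genotypes[index][None, :]
    else:
        labels = list(populations)
        pops = sorted(set(labels))
        if len(pops) != 2:
            raise ValueError("exactly two populations required")
        cols1 = np.array([i for i, l in enumerate(labels) if l == pops[0]])
        cols2 = np.array([i for i, l in enumerate(labels) if l == pops[1]])
        g = np.asarray(site.genotypes, dtype=np.int8)[None, :]

    a, b, c, p1, p2, _, _ = wc_components(g, cols1, cols2)
    denom = a[0] + b[0] + c[0]
    if not np.isfinite(denom) or denom == 0:
        fst = float("nan")
    else:
        fst = float(a[0] / denom)
    fixed = bool(_fixed_mask(g, cols1, cols2)[0])
    return SiteDivergence(site.scaffold, site.position, fst,
                          float(p1[0]), float(p2[0]), fixed)


def site_divergence_table(matrix: GenotypeMatrix,
                          populations: Sequence[str] = None) -> pd.DataFrame:
    """Per-site divergence table for the whole matrix (vectorized)."""
    pops = populations or sorted(set(matrix.populations.values()))
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    cols1 = matrix.pop_columns(pops[0])
    cols2 = matrix.pop_columns(pops[1])
    a, b, c, p1, p2, _, _ = wc_components(matrix.genotypes, cols1, cols2)
    denom = a + b + c
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    fixed = _fixed_mask(matrix.genotypes, cols1, cols2)
    df = matrix.sites[["scaffold", "position"]].copy()
    df["p1"] = p1
    df["p2"] = p2
    df["fst"] = fst
    df["is_fixed"] = fixed
    df["wc_a"] = a
    df["wc_abc"] = denom
    return df


def detect_fixed_snps(matrix: GenotypeMatrix,
                      populations: Sequence[str] = None) -> list:
    """SiteDivergence records for every fixed difference in the matrix."""
    table = site_divergence_table(matrix, populations)
    out = []
    for row in table[table["is_fixed"]].itertuples():
        out.append(SiteDivergence(row.scaffold, int(row.position),
                                  float(row.fst), float(row.p1),
                                  float(row.p2), True))
    return out


def window_divergence(matrix: GenotypeMatrix, populations=None,
                      window_bp: int = 10_000, step_bp: int = None,
                      min_sites: int = 1) -> list:
    """Tiled (or sliding) window Fst (ratio of sums) and Dxy.

    Windows tile each scaffold from coordinate 1; windows with fewer than
    ``min_sites`` analyzed sites are omitted.
    """
    step_bp = step_bp or window_bp
    if not window_bp >= step_bp >= 1:
        raise ValueError("require window_bp >= step_bp >= 1")
    table = site_divergence_table(matrix, populations)
    with np.errstate(invalid="ignore"):
        table["dxy_site"] = (table["p1"] * (1 - table["p2"])
                             + table["p2"] * (1 - table["p1"]))
    out = []
    for scaf, sub in table.groupby("scaffold", sort=True):
        pos = sub["position"].to_numpy()
        last = int(pos.max())
        start = 1
        while start <= last:
            end = start + window_bp - 1
            in_win = (pos >= start) & (pos <= end)
            ok = in_win & np.isfinite(sub["dxy_site"].to_numpy())
            n = int(ok.sum())
            if n >= min_sites:
                num = np.nansum(sub["wc_a"].to_numpy()[ok])
                den = np.nansum(sub["wc_abc"].to_numpy()[ok])
                fst_w = float(num / den) if den != 0 else float("nan")
                dxy = float(np.mean(sub["dxy_site"].to_numpy()[ok]))
                out.append(DivergenceWindow(scaf, start, end, n, fst_w, dxy))
            else:
                logger.debug("window %s:%d-%d omitted (%d sites)",
                             scaf, start, end, n)
            start += step_bp
    return out


def windows_to_frame(windows: Sequence[DivergenceWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [(w.scaffold, w.start, w.end, w.n_sites, w.fst_window, w.dxy)
         for w in windows],
        columns=["scaffold", "start", "end", "n_sites", "fst", "dxy"])


# ---------------------------------------------------------------------------
# structural-variant fixation across call sets


def _sv_match(r1, r2, tol: int, min_ro: float) -> bool:
    """Two SV records describe the same variant: same type/scaffold, both
    breakpoints within ``tol`` bp, reciprocal overlap >= ``min_ro``."""
    if r1[0] != r2[0] or r1[3] != r2[3]:
        return False
    if abs(r1[1] - r2[1]) > tol or abs(r1[2] - r2[2]) > tol:
        return False
    inter = min(r1[2], r2[2]) - max(r1[1], r2[1]) + 1
    if inter <= 0:
        return False
    len1 = r1[2] - r1[1] + 1
    len2 = r2[2] - r2[1] + 1
    return inter >= min_ro * len1 and inter >= min_ro * len2


def match_sv_records(call_sets: Sequence[SVCallSet], tol: int,
                     min_ro: float) -> list:
    """Cluster records across call sets; returns a list of clusters, each a
    list of (call_set_index, record_index)."""
    pooled = []
    for ci, cs in enumerate(call_sets):
        recs = cs.records
        scafs = recs["scaffold"].to_list()
        types = recs["sv_type"].to_list()
        arr = recs[["start", "end"]].to_numpy()
        for ri in range(len(recs)):
            pooled.append((scafs[ri], int(arr[ri, 0]), int(arr[ri, 1]),
                           types[ri], ci, ri))
    pooled.sort(key=lambda t: (t[3], t[0], t[1], t[2]))
    clusters = []
    open_clusters = []  # [(rep_tuple, member_list)]
    for rec in pooled:
        key = (rec[0], rec[1], rec[2], rec[3])
        # close clusters that can no longer match (sorted by start)
        still_open = []
        for rep, members in open_clusters:
            if rep[3] != rec[3] or rep[0] != rec[0] or rec[1] - rep[1] > tol:
                clusters.append(members)
            else:
                still_open.append((rep, members))
        open_clusters = still_open
        placed = False
        for rep, members in open_clusters:
            if _sv_match(rep, key, tol, min_ro):
                members.append((rec[4], rec[5]))
                placed = True
                break
        if not placed:
            open_clusters.append((key, [(rec[4], rec[5])]))
    clusters.extend(members for _, members in open_clusters)
    return clusters


def fixed_structural_variants(call_sets: Sequence[SVCallSet],
                              populations: dict, filters=None) -> list:
    """SVs fixed between the two populations, shared across all call sets.

    A cluster of matched records is fixed iff a record from every call set is
    present and, in every record, all individuals of one population carry the
    alternate allele while all individuals of the other are homozygous
    reference.  Output is ordered by (scaffold, start) and invariant to
    call-set ordering.
    """
    from .config import FilterConfig

    filters = filters or FilterConfig()
    for cs in call_sets:
        for s in cs.samples:
            if s not in populations:
                raise ValueError(f"call set {cs.source_id}: unknown sample {s!r}")
    pops = sorted(set(populations.values()))
    if len(pops) != 2:
        raise ValueError("exactly two populations required")
    clusters = match_sv_records(call_sets, filters.sv_breakpoint_tol,
                                filters.sv_min_reciprocal_overlap)
    n_sets = len(call_sets)
    fixed = []
    for members in clusters:
        if {ci for ci, _ in members} != set(range(n_sets)):
            continue
        alt_pop = None
        ok = True
        seen = set()
        for ci, ri in members:
            cs = call_sets[ci]
            g = cs.genotypes[ri]
            carriers = {p: [] for p in pops}
            for s, gt in zip(cs.samples, g):
                carriers[populations[s]].append(int(gt))
                seen.add(s)
            state = {}
            for p in pops:
                gts = carriers[p]
                if not gts:
                    continue
                if all(gt in (HET, HOM_ALT) for gt in gts):
                    state[p] = "alt"
                elif all(gt == HOM_REF for gt in gts):
                    state[p] = "ref"
                else:
                    state[p] = "mixed"
            alts = [p for p, st in state.items() if st == "alt"]
            refs = [p for p, st in state.items() if st == "ref"]
            if len(alts) == 1 and len(refs) == len(state) - 1:
                if alt_pop is None:
                    alt_pop = alts[0]
                elif alt_pop != alts[0]:
                    ok = False
                    break
            else:
                ok = False
                break
        if not ok or alt_pop is None:
            continue
        if seen != set(populations):
            continue  # some individual never genotyped for this variant
        # representative record: first call set's member
        ci, ri = sorted(members)[0]
        fixed.append(call_sets[ci].record(ri))
    fixed.sort(key=lambda sv: (sv.scaffold, sv.start, sv.end))
    return fixed


def fixed_svs_to_frame(svs: Sequence[StructuralVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        [(sv.scaffold, sv.start, sv.end, sv.sv_type, sv.length) for sv in svs],
        columns=["scaffold", "start", "end", "type", "length"])
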