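"""An ms-compatible coalescent simulator with recombination.

Implements Hudson's coalescent for a structured population with the exact
flag subset of the two simulation command lines used by the analysis:
``-t -r -I -m -n -en -ej``.  Time is measured in units of 4N0 generations;
a pair of lineages in a deme of relative size x coalesces at rate 2/x,
crossovers occur at total rate rho times the fraction of the region spanned
by a lineage's ancestral material (trapped material included), migration of
a lineage from deme i to deme j occurs at rate m_ij/2 where m_ij = 4N0 m,
and mutations follow the infinite-sites model at rate theta per unit time
per unit region span of tracked ancestral material.

Ancestral material is tracked as intervals over [0, 1), each carrying the
set of sampled haplotypes below it (a bitmask).  Intervals that reach their
local MRCA (bitmask = all samples) are dropped, so mutation placement on the
branch log below automatically yields only segregating sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .ms_io import SimReplicate

_SUPPORTED = {"-t", "-r", "-I", "-m", "-n", "-en", "-ej"}


@dataclass(frozen=True)
class DemographicEvent:
    time: float
    kind: str                 # "en" (size change) or "ej" (deme join)
    deme: int                 # 0-based
    size: float = 0.0         # for "en"
    dest: int = -1            # for "ej"


@dataclass
class DemographicModel:
    """Parsed ms-style simulation specification."""

    n_sam: int
    n_reps: int
    theta: float = 0.0
    rho: float = 0.0
    n_sites: int = 2
    n_pop: int = 1
    subsizes: tuple[int, ...] = ()
    symmetric_mig: float = 0.0
    mig_entries: tuple[tuple[int, int, float], ...] = ()   # 0-based (i, j, 4N0m)
    size_now: tuple[tuple[int, float], ...] = ()           # 0-based (deme, x)
    events: tuple[DemographicEvent, ...] = ()

    def __post_init__(self) -> None:
        if not self.subsizes:
            self.subsizes = (self.n_sam,)
        if sum(self.subsizes) != self.n_sam:
            raise ValueError(
                f"-I subsample sizes {self.subsizes} do not sum to n_sam {self.n_sam}"
            )
        if any(e.time < 0 for e in self.events):
            raise ValueError("event times must be >= 0")
        self.events = tuple(sorted(self.events, key=lambda e: e.time))

    def migration_matrix(self) -> np.ndarray:
        """Backward migration rates m_ij = 4N0 m (lineage moves i -> j)."""
        m = np.zeros((self.n_pop, self.n_pop))
        if self.n_pop > 1 and self.symmetric_mig > 0:
            m[:] = self.symmetric_mig / (self.n_pop - 1)
            np.fill_diagonal(m, 0.0)
        for i, j, x in self.mig_entries:
            m[i, j] = x
        return m

    def initial_sizes(self) -> np.ndarray:
        x = np.ones(self.n_pop)
        for deme, size in self.size_now:
            x[deme] = size
        return x

    def sample_demes(self) -> np.ndarray:
        return np.repeat(np.arange(self.n_pop), self.subsizes)


def parse_ms_args(command: str) -> DemographicModel:
    """Parse an ms command line (supported flags: -t -r -I -m -n -en -ej)."""
    toks = command.split()
    # strip a leading program token such as "./ms" or "ms"
    if toks and not toks[0].lstrip("./").replace(".", "").isdigit():
        toks = toks[1:]
    if len(toks) < 2:
        raise ValueError("command must start with '<ms> n_sam n_reps'")
    n_sam, n_reps = int(toks[0]), int(toks[1])
    i = 2
    kw: dict = dict(n_sam=n_sam, n_reps=n_reps)
    mig_entries: list[tuple[int, int, float]] = []
    size_now: list[tuple[int, float]] = []
    events: list[DemographicEvent] = []
    while i < len(toks):
        flag = toks[i]
        if flag not in _SUPPORTED:
            raise ValueError(f"unsupported ms flag: {flag}")
        try:
            if flag == "-t":
                kw["theta"] = float(toks[i + 1]); i += 2
            elif flag == "-r":
                kw["rho"] = float(toks[i + 1])
                kw["n_sites"] = int(toks[i + 2]); i += 3
            elif flag == "-I":
                npop = int(toks[i + 1])
                sizes = tuple(int(toks[i + 2 + k]) for k in range(npop))
                i += 2 + npop
                kw["n_pop"] = npop
                kw["subsizes"] = sizes
                # optional trailing symmetric migration parameter 4N0m
                if i < len(toks) and not toks[i].startswith("-"):
                    kw["symmetric_mig"] = float(toks[i]); i += 1
            elif flag == "-m":
                mig_entries.append(
                    (int(toks[i + 1]) - 1, int(toks[i + 2]) - 1, float(toks[i + 3]))
                )
                i += 4
            elif flag == "-n":
                size_now.append((int(toks[i + 1]) - 1, float(toks[i + 2])))
                i += 3
            elif flag == "-en":
                events.append(
                    DemographicEvent(
                        time=float(toks[i + 1]), kind="en",
                        deme=int(toks[i + 2]) - 1, size=float(toks[i + 3]),
                    )
                )
                i += 4
            elif flag == "-ej":
                events.append(
                    DemographicEvent(
                        time=float(toks[i + 1]), kind="ej",
                        deme=int(toks[i + 2]) - 1, dest=int(toks[i + 3]) - 1,
                    )
                )
                i += 4
        except (IndexError, ValueError) as exc:
            if isinstance(exc, ValueError) and "unsupported" in str(exc):
                raise
            raise ValueError(f"malformed arguments for flag {flag}") from exc
    return DemographicModel(
        mig_entries=tuple(mig_entries), size_now=tuple(size_now),
        events=tuple(events), **kw,
    )


# ---------------------------------------------------------------------------
# Hudson's algorithm
# ---------------------------------------------------------------------------

class _Lineage:
    __slots__ = ("deme", "birth", "segs")

    def __init__(self, deme: int, birth: float, segs: list) -> None:
        self.deme = deme
        self.birth = birth
        self.segs = segs        # list of [left, right, mask], sorted, disjoint

    def span(self) -> float:
        return self.segs[-1][1] - self.segs[0][0]


def _merge_segments(a: list, b: list, full_mask: int) -> list:
    """Union two disjoint-interval segment lists; overlapping parts get the
    union of the descendant bitmasks; intervals reaching the full sample mask
    (local MRCA) are dropped.  Adjacent intervals with equal masks fuse."""
    bounds = sorted({x for l, r, _ in a + b for x in (l, r)})
    out: list = []
    ia = ib = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        mid = (lo + hi) * 0.5
        mask = 0
        while ia < len(a) and a[ia][1] <= lo:
            ia += 1
        if ia < len(a) and a[ia][0] <= mid < a[ia][1]:
            mask |= a[ia][2]
        while ib < len(b) and b[ib][1] <= lo:
            ib += 1
        if ib < len(b) and b[ib][0] <= mid < b[ib][1]:
            mask |= b[ib][2]
        if mask == 0 or mask == full_mask:
            continue
        if out and out[-1][1] == lo and out[-1][2] == mask:
            out[-1][1] = hi
        else:
            out.append([lo, hi, mask])
    return out


def _split_segments(segs: list, bp: float) -> tuple[list, list]:
    left: list = []
    right: list = []
    for l, r, m in segs:
        if r <= bp:
            left.append([l, r, m])
        elif l >= bp:
            right.append([l, r, m])
        else:
            left.append([l, bp, m])
            right.append([bp, r, m])
    return left, right


def _simulate_one(
    model: DemographicModel, rng: np.random.Generator, max_events: int
) -> tuple[np.ndarray, list[int]]:
    """Run one replicate; return (positions, site bitmasks)."""
    n = model.n_sam
    npop = model.n_pop
    full_mask = (1 << n) - 1
    sizes = model.initial_sizes().tolist()
    mig = model.migration_matrix().tolist()
    pending = list(model.events)

    lineages: dict[int, _Lineage] = {}
    deme_ids: list[list[int]] = [[] for _ in range(npop)]
    next_id = 0
    sample_demes = model.sample_demes()
    for s in range(n):
        lin = _Lineage(int(sample_demes[s]), 0.0, [[0.0, 1.0, 1 << s]])
        lineages[next_id] = lin
        deme_ids[lin.deme].append(next_id)
        next_id += 1

    # branch log: (duration, left, right, mask) per destroyed lineage segment
    log_dur: list[float] = []
    log_l: list[float] = []
    log_r: list[float] = []
    log_mask: list[int] = []

    W = float(n)  # total recombination span (sum of lineage spans)
    t = 0.0
    n_events = 0
    expo = rng.exponential
    unif = rng.random

    def destroy(lid: int) -> _Lineage:
        nonlocal W
        lin = lineages.pop(lid)
        deme_ids[lin.deme].remove(lid)
        W -= lin.span()
        dt = t - lin.birth
        if dt > 0:
            for l, r, m in lin.segs:
                log_dur.append(dt)
                log_l.append(l)
                log_r.append(r)
                log_mask.append(m)
        return lin

    def create(deme: int, segs: list) -> None:
        nonlocal W, next_id
        if not segs:
            return
        lin = _Lineage(deme, t, segs)
        lineages[next_id] = lin
        deme_ids[deme].append(next_id)
        W += lin.span()
        next_id += 1

    while lineages:
        n_events += 1
        if n_events > max_events:
            raise RuntimeError(
                f"simulation exceeded {max_events} events without coalescing "
                "(zero-size or isolated-deme pathology?)"
            )
        # rates under the current (piecewise-constant) demography
        coal_rates = [
            len(ids) * (len(ids) - 1) / sizes[k] for k, ids in enumerate(deme_ids)
        ]
        mig_out = [sum(mig[k][j] for j in range(npop) if j != k) for k in range(npop)]
        mig_rates = [len(deme_ids[k]) * mig_out[k] for k in range(npop)]
        rec_rate = model.rho * W
        total = sum(coal_rates) + sum(mig_rates) + rec_rate

        next_ev_t = pending[0].time if pending else math.inf
        if total <= 0.0:
            if math.isinf(next_ev_t):
                raise RuntimeError(
                    "no possible events but uncoalesced lineages remain"
                )
            t = next_ev_t
        else:
            dt = expo(1.0 / total)
            if t + dt >= next_ev_t:
                t = next_ev_t
            else:
                t += dt
                u = unif() * total
                acc = 0.0
                done = False
                # coalescence
                for k in range(npop):
                    acc += coal_rates[k]
                    if u < acc:
                        ids = deme_ids[k]
                        i1 = int(unif() * len(ids))
                        i2 = int(unif() * (len(ids) - 1))
                        if i2 >= i1:
                            i2 += 1
                        id_a, id_b = ids[i1], ids[i2]
                        la = destroy(id_a)
                        lb = destroy(id_b)
                        done = True
                        break
                if done:
                    merged = _merge_segments(la.segs, lb.segs, full_mask)
                    create(k, merged)
                    continue
                # migration
                for k in range(npop):
                    acc += mig_rates[k]
                    if u < acc:
                        ids = deme_ids[k]
                        lid = ids[int(unif() * len(ids))]
                        # destination proportional to m[k][j]
                        v = unif() * mig_out[k]
                        a2 = 0.0
                        dest = k
                        for j in range(npop):
                            if j == k:
                                continue
                            a2 += mig[k][j]
                            if v < a2:
                                dest = j
                                break
                        lin = lineages[lid]
                        deme_ids[k].remove(lid)
                        lin.deme = dest
                        deme_ids[dest].append(lid)
                        done = True
                        break
                if done:
                    continue
                # recombination: pick lineage proportional to span
                v = unif() * W
                acc2 = 0.0
                chosen = None
                for lid, lin in lineages.items():
                    acc2 += lin.span()
                    if v < acc2:
                        chosen = lid
                        break
                if chosen is None:  # numerical edge
                    chosen = lid
                lin = lineages[chosen]
                lo, hi = lin.segs[0][0], lin.segs[-1][1]
                bp = lo + unif() * (hi - lo)
                if bp <= lo or bp >= hi:
                    continue
                deme = lin.deme
                old = destroy(chosen)
                left, right = _split_segments(old.segs, bp)
                create(deme, left)
                create(deme, right)
                continue

        # apply demographic events scheduled at time t
        while pending and pending[0].time <= t:
            ev = pending.pop(0)
            if ev.kind == "en":
                sizes[ev.deme] = ev.size
            elif ev.kind == "ej":
                for lid in list(deme_ids[ev.deme]):
                    deme_ids[ev.deme].remove(lid)
                    lineages[lid].deme = ev.dest
                    deme_ids[ev.dest].append(lid)
                for k in range(npop):
                    mig[k][ev.deme] = 0.0
                    mig[ev.deme][k] = 0.0

    # ---- drop mutations on the branch log (infinite sites) ----------------
    if model.theta <= 0 or not log_dur:
        return np.empty(0), []
    dur = np.asarray(log_dur)
    seg_l = np.asarray(log_l)
    seg_r = np.asarray(log_r)
    lam = model.theta * dur * (seg_r - seg_l)
    counts = rng.poisson(lam)
    positions: list[float] = []
    masks: list[int] = []
    for idx in np.flatnonzero(counts):
        c = int(counts[idx])
        pos = seg_l[idx] + rng.random(c) * (seg_r[idx] - seg_l[idx])
        m = log_mask[idx]
        for p in pos:
            positions.append(float(p))
            masks.append(m)
    if not positions:
        return np.empty(0), []
    order = np.argsort(positions, kind="stable")
    pos_arr = np.asarray(positions)[order]
    masks = [masks[i] for i in order]
    return pos_arr, masks


def _masks_to_matrix(masks: list[int], n: int) -> np.ndarray:
    nbytes = (n + 7) // 8
    out = np.zeros((len(masks), n), dtype=np.uint8)
    for j, m in enumerate(masks):
        bits = np.frombuffer(m.to_bytes(nbytes, "little"), dtype=np.uint8)
        out[j] = np.unpackbits(bits, bitorder="little")[:n]
    return out.T.copy()  # (n_hap, n_sites)


def simulate(
    model: DemographicModel,
    seed: int,
    n_reps: Optional[int] = None,
    max_events: int = 5_000_000,
) -> Iterator[SimReplicate]:
    """Simulate replicates under ``model``.

    Deterministic for a fixed seed: per-replicate generators are derived by
    spawning numpy's SeedSequence, so each replicate is independently
    reproducible regardless of how the stream is consumed.
    """
    reps = model.n_reps if n_reps is None else n_reps
    demes = model.sample_demes()
    root = np.random.SeedSequence(seed)
    for k, child in enumerate(root.spawn(reps)):
        rng = np.random.Generator(np.random.PCG64(child))
        positions, masks = _simulate_one(model, rng, max_events)
        alleles = _masks_to_matrix(masks, model.n_sam)
        yield SimReplicate(positions, alleles, demes, seed=k)


def subpop_frequency(rep: SimReplicate, deme: int, site: int) -> float:
    """Derived-allele fraction at ``site`` among one deme's haplotypes."""
    if deme not in rep.demes:
        raise ValueError(f"deme {deme} not present in replicate")
    sub = rep.alleles[rep.demes == deme, site]
    return float(sub.mean())


def deme_frequencies(rep: SimReplicate, deme: int) -> np.ndarray:
    """Derived-allele fraction in ``deme`` for every site at once."""
    sub = rep.alleles[rep.demes == deme]
    if sub.shape[0] == 0:
        raise ValueError(f"deme {deme} not present in replicate")
    return sub.mean(axis=0)
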