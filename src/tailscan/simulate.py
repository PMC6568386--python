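"""Forward Wright-Fisher simulator of two diverged diploid populations.

Emulates medium-density SNP-array data (a few tens of diploids per
population, thousands of biallelic markers per chromosome) with realistic
linkage disequilibrium: founder haplotypes drawn with uniform allele
frequencies are recombined into an ancestral mosaic population (geometric
segment lengths create LD), the population splits in two, and each
population then evolves independently under random mating with Poisson
crossovers.  An optional selective sweep applies genic fitness 1 : 1+s :
1+2s for the favoured allele at a chosen focal SNP in one population only.
Output is a phased :class:`~tailscan.genotype_io.GenotypeDataset` plus a
truth record with the realized focal-allele frequency trajectories; a given
seed reproduces the data bit for bit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from tailscan.genotype_io import MISSING, GenotypeDataset, write_plink


@dataclass(frozen=True)
class SweepSpec:
    """A recent selective sweep in one of the two populations.

    Selection (fitness 1 : 1+s : 1+2s by favoured-allele count) acts in one
    population from ``onset_generation`` until sampling; by default it
    switches on 45 generations before the end.  By default (``init_freq``
    None) the favoured allele is absent until onset and is then introduced
    as a single copy on one haplotype of the swept population — a hard
    sweep whose carriers share a tract of order 1/(2 r t) around the focal
    SNP.  Setting ``init_freq`` instead draws the allele at that founder
    frequency (a sweep from standing variation, typically soft).

    The scenario this models is a strong sweep still in progress or just
    short of fixation at sampling time — the regime extended-haplotype
    statistics are designed for: a sweep finished long before sampling
    leaves no haplotype signature, and a fully fixed sweep leaves the
    surrounding markers monomorphic and unscannable.  Because a single new
    copy is usually lost to drift, the post-onset phase is re-drawn
    deterministically (seeded by seed and attempt counter, shared pre-onset
    history) until the favoured allele's final frequency lands in
    [``min_final_freq``, ``max_final_freq``]; the accepted attempt number
    is part of the truth record.
    """

    chrom: int  # 1-based chromosome number
    pos_bp: int  # target position; the nearest marker becomes the focal SNP
    s: float  # selection coefficient
    population: int = 1  # 1 or 2
    onset_generation: int | None = None  # default: generations_split - 45
    init_freq: float | None = None  # None: single new copy at onset
    min_final_freq: float = 0.72
    max_final_freq: float = 0.88
    max_redraws: int = 60


@dataclass(frozen=True)
class SimParams:
    """Study-scale defaults: two populations evolving at effective size
    ``ne`` = 800 diploids for 100 generations after the split, with ``n1``
    and ``n2`` = 50 diploids sampled at the end and genotyped at 2,000 SNPs
    on each of 3 chromosomes of 100 Mb.  Keeping ``ne`` above the sample
    size reproduces array-scale background LD and between-breed
    differentiation; setting ``ne`` equal to the sample size instead yields
    unrealistically strong drift.
    """

    n_founder_haplotypes: int = 20
    n1: int = 50
    n2: int = 50
    ne: int = 800
    n_chrom: int = 3
    snps_per_chrom: int = 2_000
    chrom_length_bp: int = 100_000_000
    generations_split: int = 100
    recomb_rate_per_bp: float = 1e-8
    founder_segment_mean_snps: int = 10
    sweep: SweepSpec | None = None
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("population sizes must be >= 2")
        if self.ne < max(self.n1, self.n2):
            raise ValueError("ne must be >= the sampled population sizes")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must be in [0,1]")
        if self.sweep is not None and self.sweep.s < 0:
            raise ValueError("selection coefficient must be >= 0")


@dataclass
class SimTruth:
    params: SimParams
    focal_snp_id: str | None
    focal_chrom: str | None
    focal_pos_bp: int | None
    s: float
    swept_population: int | None
    trajectory_pop1: list[float] = field(default_factory=list)
    trajectory_pop2: list[float] = field(default_factory=list)
    focal_lost: bool = False
    attempt: int = 0

    def to_text(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"seed\t{self.params.seed}\n")
            fh.write(f"s\t{self.s}\n")
            fh.write(f"focal_snp_id\t{self.focal_snp_id}\n")
            fh.write(f"focal_chrom\t{self.focal_chrom}\n")
            fh.write(f"focal_pos_bp\t{self.focal_pos_bp}\n")
            fh.write(f"swept_population\t{self.swept_population}\n")
            fh.write(f"focal_lost\t{self.focal_lost}\n")
            fh.write(f"attempt\t{self.attempt}\n")
            fh.write("trajectory_pop1\t" + ",".join(f"{x:.6f}" for x in self.trajectory_pop1) + "\n")
            fh.write("trajectory_pop2\t" + ",".join(f"{x:.6f}" for x in self.trajectory_pop2) + "\n")


def _mosaic_haplotypes(rng, founders: np.ndarray, n_hap: int, mean_seg_snps: int) -> np.ndarray:
    """Build haplotypes by copying founder segments with geometric lengths."""
    n_founders, m = founders.shape
    out = np.empty((n_hap, m), dtype=np.uint8)
    for h in range(n_hap):
        j = 0
        while j < m:
            seg = rng.geometric(1.0 / mean_seg_snps)
            src = rng.integers(n_founders)
            out[h, j : j + seg] = founders[src, j : j + seg]
            j += seg
    return out


def _gamete(rng, h0: np.ndarray, h1: np.ndarray, pos: np.ndarray, rate: float, length: int) -> np.ndarray:
    """One recombinant gamete: Poisson crossover count, uniform positions."""
    n_x = rng.poisson(rate * length)
    if n_x == 0:
        return (h0 if rng.integers(2) == 0 else h1).copy()
    breaks = np.sort(rng.integers(1, length + 1, size=n_x))
    phase = np.searchsorted(breaks, pos, side="left") % 2
    if rng.integers(2) == 1:
        phase = 1 - phase
    return np.where(phase == 0, h0, h1).astype(np.uint8)


def _next_generation(rng, haps: list[np.ndarray], pos_list: list[np.ndarray], lengths, rate, n_diploid, fitness):
    """Random mating with fitness-weighted parent sampling; returns per-chrom
    haplotype arrays for the offspring generation.

    Gamete construction is vectorized over the common crossover counts (0
    and 1 per chromosome dominate at ~1 expected crossover / 100 Mb); only
    multi-crossover gametes fall back to the per-gamete path.
    """
    probs = fitness / fitness.sum()
    n_gam = 2 * n_diploid
    # gamete g comes from parent[g]; children 2i,2i+1 <- (father, mother)
    parents = rng.choice(len(fitness), size=(n_diploid, 2), p=probs).ravel()
    out = []
    for c, h in enumerate(haps):
        pos, length = pos_list[c], lengths[c]
        n_x = rng.poisson(rate * length, size=n_gam)
        start = rng.integers(2, size=n_gam)  # which parental haplotype leads
        res = np.empty((n_gam, h.shape[1]), dtype=np.uint8)
        lead = 2 * parents + start
        none = np.flatnonzero(n_x == 0)
        res[none] = h[lead[none]]
        one = np.flatnonzero(n_x == 1)
        if one.size:
            cuts = np.searchsorted(pos, rng.integers(1, length + 1, size=one.size), side="left")
            for g, cut in zip(one, cuts):
                res[g, :cut] = h[lead[g], :cut]
                res[g, cut:] = h[2 * parents[g] + 1 - start[g], cut:]
        for g in np.flatnonzero(n_x >= 2):
            breaks = np.sort(rng.integers(1, length + 1, size=n_x[g]))
            phase = (np.searchsorted(breaks, pos, side="left") + start[g]) % 2
            res[g] = np.where(phase == 0, h[2 * parents[g]], h[2 * parents[g] + 1])
        out.append(res)
    return out


def simulate_two_pops(params: SimParams = SimParams()) -> tuple[GenotypeDataset, SimTruth]:
    """Run the simulation; returns a phased dataset and the truth record.

    Populations are labelled ``pop1`` and ``pop2``.  The dataset carries
    phased haplotypes (``calls`` derived from them); with
    ``missing_rate > 0`` missing calls are injected into ``calls`` and the
    phase attribute is dropped.  With a sweep, the shared pre-onset history
    is simulated once and the post-onset phase is re-drawn
    deterministically (seeded by seed and attempt counter) until the
    favoured allele's final frequency falls in the acceptance window (see
    :class:`SweepSpec`).
    """
    sweep = params.sweep
    rng = np.random.default_rng(np.random.SeedSequence([params.seed]))

    # SNP map: near-regular spacing with jitter, mirroring how genotyping
    # arrays are engineered for even genome coverage (no long marker deserts)
    chroms, positions, snp_ids = [], [], []
    for c in range(1, params.n_chrom + 1):
        m = params.snps_per_chrom
        spacing = params.chrom_length_bp / (m + 1)
        jitter = rng.uniform(-0.4, 0.4, size=m)
        pos = np.unique(((np.arange(1, m + 1) + jitter) * spacing).astype(np.int64))
        while pos.size < m:  # unique() collisions are essentially impossible at array scale
            extra = rng.integers(1, params.chrom_length_bp + 1, size=m - pos.size)
            pos = np.unique(np.concatenate([pos, extra]))
        positions.append(pos)
        chroms.extend([str(c)] * m)
        snp_ids.extend([f"snp_{c}_{k}" for k in range(m)])

    focal_chrom_idx = focal_local = None
    onset = params.generations_split
    if sweep is not None:
        focal_chrom_idx = sweep.chrom - 1
        focal_local = int(np.argmin(np.abs(positions[focal_chrom_idx] - sweep.pos_bp)))
        onset = (
            max(0, params.generations_split - 45)
            if sweep.onset_generation is None
            else sweep.onset_generation
        )

    # founders and ancestral mosaic of 2 populations x ne diploids
    hap_chrom: list[np.ndarray] = []
    for c, pos in enumerate(positions):
        freqs = rng.uniform(0.1, 0.9, size=pos.size)
        if sweep is not None and c == focal_chrom_idx:
            freqs[focal_local] = 0.0 if sweep.init_freq is None else sweep.init_freq
        founders = (rng.random((params.n_founder_haplotypes, pos.size)) < freqs).astype(np.uint8)
        hap_chrom.append(_mosaic_haplotypes(rng, founders, 4 * params.ne, params.founder_segment_mean_snps))

    # split into two evolving populations of ne diploids each
    pops = {
        1: [h[: 2 * params.ne].copy() for h in hap_chrom],
        2: [h[2 * params.ne :].copy() for h in hap_chrom],
    }
    lengths = [params.chrom_length_bp] * params.n_chrom

    def _focal_freq(pop_haps) -> float:
        return float(pop_haps[focal_chrom_idx][:, focal_local].mean())

    def _evolve(pops, rng_e, gen_from, gen_to, traj):
        """Evolve both populations in place over [gen_from, gen_to).

        Returns None (early abort) if the favoured allele dies out in the
        swept population after selection has begun — the attempt cannot
        reach the acceptance window, so the caller can retry cheaply.
        """
        for gen in range(gen_from, gen_to):
            for p in (1, 2):
                fitness = np.ones(params.ne)
                if sweep is not None and sweep.s > 0 and p == sweep.population and gen >= onset:
                    hap = pops[p][focal_chrom_idx]
                    g = hap[0::2, focal_local].astype(int) + hap[1::2, focal_local].astype(int)
                    fitness = 1.0 + sweep.s * g
                pops[p] = _next_generation(
                    rng_e, pops[p], positions, lengths, params.recomb_rate_per_bp, params.ne, fitness
                )
                if sweep is not None:
                    traj[p].append(_focal_freq(pops[p]))
            if (
                sweep is not None
                and sweep.s > 0
                and gen >= onset
                and _focal_freq(pops[sweep.population]) == 0.0
            ):
                return None
        return pops

    traj: dict[int, list[float]] = {1: [], 2: []}
    attempt = 0
    focal_lost = False
    if sweep is None:
        pops = _evolve(pops, rng, 0, params.generations_split, traj)
        rng_phase = rng
    else:
        pops = _evolve(pops, rng, 0, min(onset, params.generations_split), traj)
        snapshot = {p: [h.copy() for h in pops[p]] for p in (1, 2)}
        pre_traj = {p: list(traj[p]) for p in (1, 2)}
        n_attempts = 1 if sweep.s == 0 else sweep.max_redraws + 1
        for attempt in range(n_attempts):
            rng_phase = np.random.default_rng(np.random.SeedSequence([params.seed, attempt + 1]))
            pops = {p: [h.copy() for h in snapshot[p]] for p in (1, 2)}
            traj = {p: list(pre_traj[p]) for p in (1, 2)}
            if sweep.init_freq is None and sweep.s > 0 and onset < params.generations_split:
                # introduce the favoured variant as a single new copy
                carrier = int(rng_phase.integers(2 * params.ne))
                pops[sweep.population][focal_chrom_idx][carrier, focal_local] = 1
            evolved = _evolve(pops, rng_phase, onset, params.generations_split, traj)
            if evolved is None:
                final = 0.0
                continue
            pops = evolved
            final = _focal_freq(pops[sweep.population])
            if sweep.s == 0 or sweep.min_final_freq <= final <= sweep.max_final_freq:
                break
        else:
            focal_lost = True
            warnings.warn(
                f"favoured allele missed the frequency window in {n_attempts} attempts "
                f"(last final frequency {final:.3f}); returning the last replicate",
                stacklevel=2,
            )

    # sample n1/n2 diploids from the final generation and assemble dataset
    samples = {
        1: np.sort(rng_phase.choice(params.ne, size=params.n1, replace=False)),
        2: np.sort(rng_phase.choice(params.ne, size=params.n2, replace=False)),
    }
    rows = {p: np.column_stack([2 * samples[p], 2 * samples[p] + 1]).ravel() for p in (1, 2)}
    hap_full = np.hstack(
        [np.vstack([pops[1][c][rows[1]], pops[2][c][rows[2]]]) for c in range(params.n_chrom)]
    ).astype(np.uint8)
    calls = (hap_full[0::2] + hap_full[1::2]).astype(np.int8)
    n_total = params.n1 + params.n2
    sample_ids = [f"ind_{i + 1:03d}" for i in range(n_total)]
    groups = ["pop1"] * params.n1 + ["pop2"] * params.n2
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "snp_id": snp_ids,
            "pos_bp": np.concatenate(positions),
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    haplotypes: np.ndarray | None = hap_full
    if params.missing_rate > 0:
        mask = rng_phase.random(calls.shape) < params.missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)
        haplotypes = None
    ds = GenotypeDataset(sample_ids, groups, snps, calls, haplotypes)

    truth = SimTruth(
        params=params,
        focal_snp_id=None if sweep is None else snp_ids[focal_chrom_idx * params.snps_per_chrom + focal_local],
        focal_chrom=None if sweep is None else str(sweep.chrom),
        focal_pos_bp=None if sweep is None else int(positions[focal_chrom_idx][focal_local]),
        s=0.0 if sweep is None else sweep.s,
        swept_population=None if sweep is None else sweep.population,
        trajectory_pop1=traj[1],
        trajectory_pop2=traj[2],
        focal_lost=focal_lost,
        attempt=attempt,
    )
    return ds, truth


# ---------------------------------------------------------------------------
# Canned fixtures

_TINY_HAPLOTYPES = np.array(
    # 4 diploids x 10 SNPs; hand-checkable EHH combinatorics (see docs)
    [
        [0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        [0, 0, 0, 0, 0, 1, 0, 0, 1, 1],
        [1, 1, 0, 1, 0, 0, 1, 0, 0, 0],
        [1, 1, 0, 1, 0, 1, 1, 1, 0, 1],
        [0, 0, 1, 0, 1, 0, 0, 0, 1, 0],
        [1, 1, 1, 1, 0, 0, 1, 0, 0, 0],
        [0, 1, 0, 0, 1, 1, 0, 1, 1, 1],
        [1, 0, 1, 1, 1, 0, 1, 1, 0, 0],
    ],
    dtype=np.uint8,
)


def tiny_dataset() -> GenotypeDataset:
    """4 samples x 10 SNPs on one chromosome, phased, evenly spaced 100 kb."""
    m = _TINY_HAPLOTYPES.shape[1]
    snps = pd.DataFrame(
        {
            "chrom": ["1"] * m,
            "snp_id": [f"t{k}" for k in range(m)],
            "pos_bp": (np.arange(m) + 1) * 100_000,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    calls = (_TINY_HAPLOTYPES[0::2] + _TINY_HAPLOTYPES[1::2]).astype(np.int8)
    return GenotypeDataset(
        [f"tiny_{i}" for i in range(4)],
        ["pop1", "pop1", "pop2", "pop2"],
        snps,
        calls,
        _TINY_HAPLOTYPES.copy(),
    )


def make_fixture(name: str, out_dir: str | Path, seed: int = 42) -> dict[str, Path]:
    """Write a canned dataset (PED/MAP + truth) used by the test suite.

    Presets: ``tiny`` (4 samples x 10 SNPs, hand-checkable), ``null_scan``
    (neutral two-population simulation at default scale), ``sweep_scan``
    (selective sweep, s = 0.2, mid-chromosome-1 focal SNP in pop1).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prefix = out_dir / name
    if name == "tiny":
        ds = tiny_dataset()
        truth = SimTruth(SimParams(seed=seed), None, None, None, 0.0, None)
    elif name == "null_scan":
        ds, truth = simulate_two_pops(SimParams(seed=seed))
    elif name == "sweep_scan":
        ds, truth = simulate_two_pops(
            SimParams(seed=seed, sweep=SweepSpec(chrom=1, pos_bp=50_000_000, s=0.2, population=1))
        )
    else:
        raise ValueError(f"unknown fixture {name!r}; use tiny, null_scan or sweep_scan")
    ped, map_ = write_plink(ds, prefix)
    truth_path = prefix.with_suffix(".truth.tsv")
    truth.to_text(truth_path)
    return {"ped": ped, "map": map_, "truth": truth_path}
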