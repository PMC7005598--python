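"""Ground-truth-emitting simulator of optical-mapping reads.

Molecules are drawn uniformly from a (random or supplied) genome with
truncated-normal lengths, in-silico digested at a restriction site, and passed
through a three-channel error model: each internal true cut survives with
probability ``p_digest`` (independent Bernoulli deletion), spurious cuts are
added as a Poisson process along the molecule, and every fragment length is
perturbed by multiplicative Gaussian sizing noise truncated at three standard
deviations.  Molecule endpoints count as cut coordinates 0 and |R| but are
exempt from the error channels and from error scoring.  The emitted ground
truth records, per Rmap, the genomic interval, the true internal cut
coordinates, the provenance (true or added) of each observed cut and the
deleted true cuts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional
from zlib import crc32

import numpy as np

from .rmap_core import Rmap, RmapSet, _occurrences

__all__ = ["SimParams", "random_genome", "simulate", "simulate_dataset", "substream"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, reproducible RNG substream derived from one master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(crc32(name.encode()),))
    )


@dataclass
class SimParams:
    """Simulation parameters.

    Defaults reflect a Bionano-like regime: ~250-kbp molecules (sd 50 kbp,
    truncated at 50 kbp), true cut sites once per 10 kbp, digestion rate 0.8
    (so 20% of true cuts are missed), one added cut per 100 kbp and 5%
    multiplicative sizing noise.  Rmaps with fewer than ``min_frags``
    fragments are discarded, as tiny molecules are in practice.  When a
    genome sequence is supplied the true cuts are the occurrences of
    ``site`` (BspQI-like 7-mer by default) instead of the density process.
    """

    genome_len: int = 4_600_000
    site: str = "GCTCTTC"
    cut_density_per_10kbp: Optional[float] = 1.0
    coverage: float = 20.0
    mol_len_mean: int = 250_000
    mol_len_sd: int = 50_000
    mol_len_min: int = 50_000
    p_digest: float = 0.8
    add_rate: float = 1.0  # added cuts per 100 kbp
    sizing_sigma: float = 0.05
    min_frags: int = 10
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_digest <= 1.0:
            raise ValueError("p_digest must be in [0, 1]")
        if self.add_rate < 0 or self.sizing_sigma < 0:
            raise ValueError("add_rate and sizing_sigma must be non-negative")


def random_genome(length: int, seed: int) -> str:
    """An i.i.d. uniform A/C/G/T sequence, reproducible by seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = substream(seed, "genome")
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def simulate(genome: Optional[str], params: SimParams) -> tuple[RmapSet, dict]:
    """Draw error-bearing Rmaps from a genome until coverage is reached.

    If ``genome`` is a sequence, true cut sites are its restriction-site
    occurrences; if None, true cut sites are drawn once as a Poisson process
    of ``cut_density_per_10kbp`` over a ``genome_len``-bp coordinate space
    (one cut per 10 kbp by default, the typical density of real data).
    Returns the RmapSet plus a ground-truth dict with the genome's true cut
    positions and, per Rmap, its interval and per-cut provenance.  Truth is
    recorded before sizing noise is applied.
    """
    rng = substream(params.seed, "simulate")
    if genome is not None:
        site_positions = _occurrences(genome.upper(), params.site.upper())
        glen = len(genome)
    else:
        if not params.cut_density_per_10kbp:
            raise ValueError("need a genome sequence or a cut density")
        glen = params.genome_len
        n_sites = rng.poisson(glen * params.cut_density_per_10kbp / 10_000)
        site_positions = sorted(
            int(x) for x in set(rng.integers(1, glen, size=n_sites))
        )
    if not site_positions:
        raise ValueError("undigestible genome: restriction site never occurs")
    sites = np.asarray(site_positions)
    target_bp = params.coverage * glen
    emitted_bp = 0
    rmaps = RmapSet()
    truth_rmaps: dict[str, dict] = {}
    i = 0
    while emitted_bp < target_bp:
        mol_len = int(round(rng.normal(params.mol_len_mean, params.mol_len_sd)))
        mol_len = max(params.mol_len_min, min(mol_len, glen))
        start = int(rng.integers(0, glen - mol_len + 1))
        end = start + mol_len
        true_cuts = [int(p - start) for p in sites[(sites > start) & (sites < end)]]
        keep = rng.random(len(true_cuts)) < params.p_digest
        kept = [c for c, k in zip(true_cuts, keep) if k]
        deleted = [c for c, k in zip(true_cuts, keep) if not k]
        n_add = rng.poisson(params.add_rate * mol_len / 100_000)
        added = sorted(
            set(int(x) for x in rng.integers(1, mol_len, size=n_add)) - set(kept)
        )
        observed = sorted(set(kept) | set(added))
        cuts = [0] + observed + [mol_len]
        frags = [b - a for a, b in zip(cuts, cuts[1:])]
        if params.sizing_sigma > 0:
            eps = rng.normal(0.0, params.sizing_sigma, size=len(frags))
            eps = np.clip(eps, -3 * params.sizing_sigma, 3 * params.sizing_sigma)
            frags = [max(1, int(round(r * (1 + e)))) for r, e in zip(frags, eps)]
        if len(frags) < params.min_frags:
            continue
        rid = f"sim_{i}"
        i += 1
        rmaps.add(Rmap(rid, frags, meta={"start": start, "end": end}))
        truth_rmaps[rid] = {
            "start": start,
            "end": end,
            "true_cuts": true_cuts,
            "deleted_cuts": deleted,
            "observed_prenoise": observed,
            "provenance": ["true" if c in set(kept) else "added" for c in observed],
        }
        emitted_bp += mol_len
    truth = {
        "genome_len": glen,
        "site": params.site,
        "site_positions": [int(p) for p in site_positions],
        "rmaps": truth_rmaps,
    }
    return rmaps, truth


def simulate_dataset(
    params: SimParams, genome: Optional[str] = None
) -> tuple[RmapSet, dict, Optional[str]]:
    """Convenience wrapper around :func:`simulate`.

    In density mode (the default) no genome sequence is materialised; with
    ``cut_density_per_10kbp=None`` a random genome is generated and digested
    at ``params.site``.
    """
    if genome is None and not params.cut_density_per_10kbp:
        genome = random_genome(params.genome_len, params.seed)
    rmaps, truth = simulate(genome, params)
    return rmaps, truth, genome
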