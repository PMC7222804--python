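"""Mitochondria-like synthetic genomes with known CpG structure.

The background is a first-order Markov chain over {A,C,G,T}.  CpG depletion
is a dinucleotide property — an i.i.d. sequence cannot hold GC content
fixed while suppressing CG — so the chain is built analytically around the
two targets that matter to the detectors:

* stationary base composition pi = ((1-gc)/2, gc/2, gc/2, (1-gc)/2) over
  (A, C, G, T), i.e. GC fraction ``gc`` with C and G balanced;
* P(G | C) = oe * pi_G, which makes the expected observed/expected CpG
  ratio equal ``oe``.

Setting the C->G transition alone would perturb the stationary law, so the
G column of every other row is rescaled by beta = (1 - oe*pi_C)/(1 - pi_C)
and each row's remaining mass is spread over the other bases in proportion
to pi.  One can verify pi is then exactly stationary, so composition and
CpG density hit their targets up to sampling noise for any feasible
(gc, oe) pair.

Islands are planted by regenerating a slice of the background with
island-specific (gc, oe) — replacement, not insertion, so all coordinates
stay stable — and the truth is recorded alongside.  A canonical vertebrate
mtDNA gene order (TRNF, 12s rRNA, ..., CYTB, D-loop) provides a realistic
feature layout for annotation tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import numpy as np

from .errors import CoordinateError, ParameterError
from .seqio import Feature, FeatureTable, GenomeRecord, Interval

BASES = "ACGT"
_IDX = {b: i for i, b in enumerate(BASES)}


@dataclass(frozen=True)
class IslandSpec:
    """One planted island: position is its 1-based start."""

    position: int
    length: int
    gc: float = 0.60
    obs_exp: float = 1.2

    @property
    def interval(self) -> Interval:
        return Interval(self.position, self.position + self.length - 1)


@dataclass(frozen=True)
class SynthSpec:
    length: int = 16500
    background_gc: float = 0.40
    background_obs_exp: float = 0.25
    islands: tuple[IslandSpec, ...] = ()
    topology: str = "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.background_gc < 1:
            raise ParameterError("background_gc must be in (0, 1)")
        if self.background_obs_exp < 0:
            raise ParameterError("background_obs_exp must be >= 0")
        ivs = sorted((i.position, i.position + i.length - 1) for i in self.islands)
        for (s, e) in ivs:
            if s < 1 or e > self.length:
                raise CoordinateError(f"island {s}..{e} outside genome")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 <= e1:
                raise CoordinateError("planted islands overlap")


@dataclass(frozen=True)
class TruthTable:
    """What was planted, for scoring detector output."""

    islands: tuple[Interval, ...]
    seed: int
    features: FeatureTable | None = None


# ---------------------------------------------------------------------------
# Markov machinery

def stationary_pi(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def transition_matrix(gc: float, oe: float) -> np.ndarray:
    """Transition matrix with stationary composition ``gc`` and expected
    CpG obs/exp ``oe``; raises on infeasible combinations."""
    pi = stationary_pi(gc)
    pi_c, pi_g = pi[1], pi[2]
    t_cg = oe * pi_g                      # P(G | C)
    beta = (1 - oe * pi_c) / (1 - pi_c)   # G-column scale for rows != C
    if t_cg >= 1 or beta < 0 or beta * pi_g >= 1:
        raise ParameterError(f"infeasible combination gc={gc}, obs_exp={oe}")
    T = np.empty((4, 4))
    for x in range(4):
        g_prob = t_cg if x == _IDX["C"] else beta * pi_g
        rest = 1.0 - g_prob
        for y in range(4):
            if y == _IDX["G"]:
                T[x, y] = g_prob
            else:
                T[x, y] = rest * pi[y] / (1 - pi_g)
    return T


def _sample_chain(n: int, T: np.ndarray, pi: np.ndarray,
                  rng: np.random.Generator) -> str:
    cum = np.cumsum(T, axis=1)
    u = rng.random(n)
    states = np.empty(n, dtype=np.int64)
    states[0] = int(np.searchsorted(np.cumsum(pi), u[0], side="right"))
    prev = states[0]
    for i in range(1, n):
        prev = int(np.searchsorted(cum[prev], u[i], side="right"))
        states[i] = prev
    return "".join(BASES[s] for s in states)


# ---------------------------------------------------------------------------
# generation

def generate_background(spec: SynthSpec) -> GenomeRecord:
    """CpG-depleted background genome, deterministic under ``spec.seed``."""
    rng = np.random.default_rng([spec.seed, 0])
    T = transition_matrix(spec.background_gc, spec.background_obs_exp)
    seq = _sample_chain(spec.length, T, stationary_pi(spec.background_gc), rng)
    return GenomeRecord(id=f"synth-{spec.seed}", sequence=seq,
                        topology=spec.topology)


def plant_islands(g: GenomeRecord, spec: SynthSpec) -> tuple[GenomeRecord, TruthTable]:
    """Replace the island slices of ``g`` with CpG-enriched sequence."""
    seq = list(g.sequence)
    for k, isl in enumerate(spec.islands):
        rng = np.random.default_rng([spec.seed, 1 + k])
        T = transition_matrix(isl.gc, isl.obs_exp)
        block = _sample_chain(isl.length, T, stationary_pi(isl.gc), rng)
        seq[isl.position - 1: isl.position - 1 + isl.length] = block
    truth = TruthTable(islands=tuple(i.interval for i in spec.islands),
                       seed=spec.seed)
    return GenomeRecord(id=g.id, sequence="".join(seq),
                        topology=g.topology, strand=g.strand), truth


def generate_genome(spec: SynthSpec) -> tuple[GenomeRecord, TruthTable]:
    """Background + planted islands in one call."""
    return plant_islands(generate_background(spec), spec)


# ---------------------------------------------------------------------------
# feature layout

# canonical vertebrate mtDNA gene order with typical lengths (bp); small
# intergenic gaps appear where real genomes have them
_LAYOUT_TEMPLATE: list[tuple[str, str, int]] = [
    ("TRNF", "tRNA", 70), ("12s rRNA", "rRNA", 950), ("TRNV", "tRNA", 70),
    ("16s rRNA", "rRNA", 1550), ("TRNL1", "tRNA", 75), ("ND1", "protein_gene", 955),
    ("TRNI", "tRNA", 70), ("TRNQ", "tRNA", 70), ("TRNM", "tRNA", 70),
    ("ND2", "protein_gene", 1040), ("TRNW", "tRNA", 70), ("TRNA", "tRNA", 70),
    ("TRNN", "tRNA", 73), ("rep_origin", "rep_origin", 31), ("TRNC", "tRNA", 66),
    ("TRNY", "tRNA", 66), ("COX1", "protein_gene", 1540), ("TRNS2", "tRNA", 70),
    ("TRND", "tRNA", 68), ("COX2", "protein_gene", 684), ("TRNK", "tRNA", 70),
    ("ATP8", "protein_gene", 204), ("ATP6", "protein_gene", 680),
    ("COX3", "protein_gene", 784), ("TRNG", "tRNA", 68), ("ND3", "protein_gene", 346),
    ("TRNR", "tRNA", 65), ("ND4L", "protein_gene", 297), ("ND4", "protein_gene", 1378),
    ("TRNH", "tRNA", 69), ("TRNS1", "tRNA", 60), ("TRNL2", "tRNA", 71),
    ("ND5", "protein_gene", 1812), ("ND6", "protein_gene", 528),
    ("TRNE", "tRNA", 69), ("CYTB", "protein_gene", 1141), ("TRNT", "tRNA", 67),
    ("TRNP", "tRNA", 66),
]
# gaps (bp) after these loci, mimicking real intergenic spacers
_GAPS = {"TRNP": 0, "ND5": 2, "TRNE": 4, "COX1": 3}

_LAYOUT_MIN = sum(n for _, _, n in _LAYOUT_TEMPLATE) + sum(_GAPS.values())


def generate_feature_layout(spec: SynthSpec) -> FeatureTable:
    """Tile the genome with the canonical vertebrate gene order.

    The D-loop takes whatever remains after the last tRNA; with circular
    topology it wraps the origin (ends inside TRNF's upstream gap the way
    the human control region does).
    """
    if spec.length < _LAYOUT_MIN + 200:
        raise ParameterError(
            f"genome of {spec.length} bp too short for the canonical layout "
            f"(needs >= {_LAYOUT_MIN + 200} bp)")
    feats = []
    pos = 1
    for name, kind, n in _LAYOUT_TEMPLATE:
        feats.append(Feature(name=name, kind=kind, start=pos, end=pos + n - 1))
        pos += n + _GAPS.get(name, 0)
    if spec.topology == "circular":
        # wrap ~60 bp of control region past the origin
        feats.append(Feature(name="D-LOOP", kind="noncoding",
                             start=pos, end=60, wraps_origin=True))
    else:
        feats.append(Feature(name="D-LOOP", kind="noncoding",
                             start=pos, end=spec.length))
    return FeatureTable(feats, genome_length=spec.length)


# ---------------------------------------------------------------------------
# emission

def write_truth_tsv(truth: TruthTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("start\tend\tseed\n")
        for iv in truth.islands:
            fh.write(f"{iv.start}\t{iv.end}\t{truth.seed}\n")


def empirical_stats(g: GenomeRecord) -> tuple[float, float]:
    """(GC fraction, obs/exp CpG ratio) of a genome — for fidelity checks."""
    s = g.sequence
    n_c, n_g = s.count("C"), s.count("G")
    gc = (n_c + n_g) / len(s)
    oe = (s.count("CG") * len(s) / (n_c * n_g)) if n_c and n_g else 0.0
    return gc, oe
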