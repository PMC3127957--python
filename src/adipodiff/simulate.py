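"""Synthetic data with known ground truth for every pipeline stage.

The generator emulates the design of a replicated two-colour microarray
differentiation study: three independent experiments, seven time points
(d0, d1, d2, d3, d4, d6, d10) of log2(Cy5/Cy3) ratios per EST, dye-swap
partner arrays carrying the sign-flipped raw signal, and replicate spots
per EST.  Non-null genes follow one of six temporal archetypes (two
mitotic-clonal-expansion peaks at d1/d3, late induction, repression, ...)
with additive Gaussian noise on the log2 scale; null genes have all-zero
means.  Companion generators produce a 3-time-point perturbation pair
(knockout vs wild-type) with planted up/down genes, promoter sequences
with planted motif instances, and a toy GO annotation with planted
enriched terms.  Every generated entity is covered by a returned truth
table, and a fixed seed reproduces each dataset exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pwm import BASES, PwmModel, reverse_complement

__all__ = [
    "SimulationConfig",
    "DEFAULT_ARCHETYPES",
    "TIME_POINTS",
    "PERTURBATION_TIME_POINTS",
    "simulate_timecourse",
    "simulate_perturbation_pair",
    "simulate_promoters",
    "simulate_go_annotation",
    "write_fasta",
]

#: sampling days of the differentiation time course
TIME_POINTS = (0, 1, 2, 3, 4, 6, 10)
#: sampling days of the perturbation comparison
PERTURBATION_TIME_POINTS = (1, 3, 8)

#: six temporal archetypes (log2 fold change vs the preconfluent stage):
#: A mid-stage induction, B two clonal-expansion peaks at d1/d3,
#: C sustained repression, D early transient induction, E late switch
#: from repression to induction, F monotone late induction
DEFAULT_ARCHETYPES: tuple[tuple[float, ...], ...] = (
    (0.0, 0.5, 1.5, 2.5, 2.5, 2.0, 1.5),
    (0.0, 2.5, 0.5, 2.5, 0.5, 0.0, 0.0),
    (0.0, -1.5, -2.0, -2.5, -2.0, -2.0, -2.0),
    (0.0, 2.0, 2.0, 1.5, 1.0, 0.5, 0.0),
    (0.0, -2.0, -1.0, 0.0, 1.0, 2.0, 2.5),
    (0.0, 0.0, 0.5, 1.0, 2.0, 3.0, 3.5),
)


@dataclass
class SimulationConfig:
    """Ground-truth design shared by all generators.

    Defaults reproduce the standard study conditions: 1000 genes of which
    400 are null, six archetypes, noise SD 0.3 log2 units, three
    biological experiments with dye-swap pairs and two replicate spots
    per EST.
    """

    n_genes: int = 1000
    n_null_genes: int = 400
    archetypes: Sequence[Sequence[float]] = DEFAULT_ARCHETYPES
    noise_sd: float = 0.3
    n_experiments: int = 3
    dye_swap: bool = True
    replicate_spots_per_est: int = 2
    seed: int = 0
    array_offset_sd: float = 0.0  # per-array additive bias (dye/batch)
    # perturbation design
    deregulation_effect: float = 2.0  # log2 units per time point
    n_up_genes: int = 100
    n_down_genes: int = 100
    n_pert_null_genes: int = 800
    # promoter design
    promoter_length: int = 5000
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    planted_motif_plan: Mapping[str, tuple[str, int]] = field(default_factory=dict)
    # GO design
    planted_go_plan: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    go_background_rate: float = 0.05

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_null_genes < 0:
            raise ValueError("gene counts must be positive")
        if self.n_null_genes > self.n_genes:
            raise ValueError("n_null_genes cannot exceed n_genes")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.archetypes:
            raise ValueError("at least one archetype is required")
        lengths = {len(a) for a in self.archetypes}
        if len(lengths) != 1:
            raise ValueError("archetype vectors must share one length")
        if self.n_experiments <= 0 or self.replicate_spots_per_est <= 0:
            raise ValueError("experiment and spot counts must be positive")
        if abs(sum(self.background_composition) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        for cluster, (term, frac) in self.planted_go_plan.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"GO plan for {cluster!r}: fraction {frac} outside [0, 1]")

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence((self.seed, salt)))


def _gene_truth(config: SimulationConfig) -> pd.DataFrame:
    """Assign each gene to an archetype (round-robin) or to the null set."""
    n_signal = config.n_genes - config.n_null_genes
    labels = []
    letters = [chr(ord("A") + i) for i in range(len(config.archetypes))]
    for i in range(config.n_genes):
        if i < n_signal:
            labels.append(letters[i % len(letters)])
        else:
            labels.append("null")
    genes = [f"est{i:05d}" for i in range(config.n_genes)]
    return pd.DataFrame({"est_id": genes, "archetype": labels})


def simulate_timecourse(config: SimulationConfig,
                        model_label: str = "MEF") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spot-level time-course dataset plus its gene -> archetype truth table.

    For each experiment and time point a forward array is generated (and,
    with ``dye_swap``, a reverse-dye partner whose raw ratios carry the
    sign-flipped signal with its own spot noise); each EST appears on
    ``replicate_spots_per_est`` spots.  Per spot the raw log2 ratio is
    ``archetype_mean + N(0, noise_sd)`` (+ an optional per-array offset),
    so the normalisation and dye-swap stages downstream have real work
    to undo.
    """
    config.validate()
    rng = config.rng(salt=1)
    truth = _gene_truth(config)
    arche = {chr(ord("A") + i): np.asarray(a, dtype=float)
             for i, a in enumerate(config.archetypes)}
    n_tp = len(config.archetypes[0])
    times = TIME_POINTS[:n_tp] if n_tp <= len(TIME_POINTS) else tuple(range(n_tp))
    means = np.zeros((config.n_genes, n_tp))
    for i, label in enumerate(truth["archetype"]):
        if label != "null":
            means[i] = arche[label]

    rows = []
    n, r = config.n_genes, config.replicate_spots_per_est
    for exp in range(1, config.n_experiments + 1):
        for ti, t in enumerate(times):
            fwd_id = f"{model_label}_e{exp}_d{t}_fwd"
            rev_id = f"{model_label}_e{exp}_d{t}_rev"
            offsets = rng.normal(0.0, config.array_offset_sd, size=2) \
                if config.array_offset_sd > 0 else np.zeros(2)
            fwd = means[:, ti][:, None] + rng.normal(0.0, config.noise_sd, (n, r))
            rows.append((exp, t, fwd_id, rev_id if config.dye_swap else "",
                         fwd + offsets[0]))
            if config.dye_swap:
                rev = -(means[:, ti][:, None] + rng.normal(0.0, config.noise_sd, (n, r)))
                rows.append((exp, t, rev_id, "", rev + offsets[1]))

    frames = []
    est_ids = truth["est_id"].to_numpy()
    for exp, t, array_id, partner, values in rows:
        frames.append(pd.DataFrame({
            "est_id": np.repeat(est_ids, r),
            "experiment": exp,
            "array_id": array_id,
            "dye_swap_partner": partner,
            "time": t,
            "spot": np.tile(np.arange(r), n),
            "flag": False,
            "log2_ratio": values.ravel(),
        }))
    spots = pd.concat(frames, ignore_index=True)
    return spots, truth


def simulate_perturbation_pair(config: SimulationConfig
                               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired 3-time-point profiles for a perturbed (A) and wild-type (B)
    model, with truth labels up / down / null.

    Every gene shares a baseline profile between the models; planted 'up'
    genes gain ``deregulation_effect`` log2 units per time point in model
    A (so at zero noise the true sum of differences is effect * T), and
    'down' genes lose it.  Returns ``(profiles_a, profiles_b, truth)``
    with the true per-gene sum of differences recorded.
    """
    config.validate()
    if config.deregulation_effect <= 0:
        raise ValueError("deregulation_effect must be > 0")
    rng = config.rng(salt=2)
    n_tp = len(PERTURBATION_TIME_POINTS)
    counts = {"up": config.n_up_genes, "down": config.n_down_genes,
              "null": config.n_pert_null_genes}
    labels = [lab for lab, c in counts.items() for _ in range(c)]
    genes = [f"pest{i:05d}" for i in range(len(labels))]

    base = rng.normal(0.0, 0.5, size=(len(genes), n_tp))
    shift = np.array([config.deregulation_effect if lab == "up"
                      else -config.deregulation_effect if lab == "down" else 0.0
                      for lab in labels])[:, None]
    noise_a = rng.normal(0.0, config.noise_sd, size=base.shape)
    noise_b = rng.normal(0.0, config.noise_sd, size=base.shape)
    cols = [f"d{t}" for t in PERTURBATION_TIME_POINTS]
    profiles_a = pd.DataFrame(base + shift + noise_a, index=genes, columns=cols)
    profiles_b = pd.DataFrame(base + noise_b, index=genes, columns=cols)
    truth = pd.DataFrame({"est_id": genes, "label": labels,
                          "true_sum_of_differences": (shift * n_tp).ravel()})
    return profiles_a, profiles_b, truth


def _sample_instance(model: PwmModel, rng: np.random.Generator,
                     consensus_only: bool) -> str:
    if consensus_only:
        return model.consensus()
    idx = [rng.choice(4, p=col / col.sum()) for col in model.freqs.T]
    return "".join(BASES[i] for i in idx)


def simulate_promoters(config: SimulationConfig, pfm_set: Mapping[str, PwmModel],
                       gene_clusters: Mapping[str, str],
                       consensus_only: bool = False
                       ) -> tuple[dict[str, str], pd.DataFrame]:
    """Promoter sequences with planted motif instances per cluster.

    ``gene_clusters`` maps each gene to its cluster (or 'null'); the
    config's ``planted_motif_plan`` maps a cluster to ``(matrix_id,
    instances_per_promoter)``.  Background is i.i.d. with the configured
    composition; planted instances are sampled per position from the
    matrix's frequency columns (or the consensus with
    ``consensus_only``), placed at uniform random non-overlapping
    positions on a uniform random strand.  Returns ``(sequences,
    placements)`` where placements records gene, matrix, position, strand
    and the planted sequence; genes without planted motifs appear with
    matrix '' so every promoter is covered by the truth table.
    """
    config.validate()
    for cluster, (matrix_id, _) in config.planted_motif_plan.items():
        if matrix_id not in pfm_set:
            raise KeyError(f"planted matrix {matrix_id!r} for cluster {cluster!r} "
                           "missing from the matrix set")
        if pfm_set[matrix_id].length > config.promoter_length:
            raise ValueError(f"matrix {matrix_id!r} longer than the promoter")

    rng = config.rng(salt=3)
    comp = np.asarray(config.background_composition)
    sequences: dict[str, str] = {}
    placements = []
    for gene in gene_clusters:
        seq = rng.choice(list(BASES), size=config.promoter_length, p=comp)
        cluster = gene_clusters[gene]
        plan = config.planted_motif_plan.get(cluster)
        if plan is None:
            sequences[gene] = "".join(seq)
            placements.append((gene, "", -1, "", ""))
            continue
        matrix_id, n_instances = plan
        model = pfm_set[matrix_id]
        L = model.length
        used: list[tuple[int, int]] = []
        for _ in range(n_instances):
            for _attempt in range(100):
                pos = int(rng.integers(0, config.promoter_length - L + 1))
                if all(pos + L <= s or pos >= e for s, e in used):
                    break
            else:
                raise RuntimeError("could not place motif without overlap")
            used.append((pos, pos + L))
            instance = _sample_instance(model, rng, consensus_only)
            strand = "+" if rng.random() < 0.5 else "-"
            planted = instance if strand == "+" else reverse_complement(instance)
            seq[pos:pos + L] = list(planted)
            placements.append((gene, matrix_id, pos, strand, instance))
        sequences[gene] = "".join(seq)
    truth = pd.DataFrame(placements, columns=["gene", "matrix_id", "position",
                                              "strand", "instance"])
    return sequences, truth


def simulate_go_annotation(genes: Iterable[str], terms: Sequence[str],
                           gene_clusters: Mapping[str, str],
                           config: SimulationConfig) -> pd.DataFrame:
    """Two-column (gene, term) annotation with planted enriched terms.

    Every term annotates each gene independently at the background rate;
    a planted term additionally annotates the stated fraction of its
    cluster's genes.  Fractions outside [0, 1] are rejected by
    ``config.validate``.
    """
    config.validate()
    rng = config.rng(salt=4)
    genes = list(genes)
    planted_by_term = {term: (cluster, frac)
                       for cluster, (term, frac) in config.planted_go_plan.items()}
    rows = []
    for term in terms:
        cluster_frac = planted_by_term.get(term)
        for gene in genes:
            if cluster_frac is not None and gene_clusters.get(gene) == cluster_frac[0]:
                annotated = rng.random() < cluster_frac[1]
            else:
                annotated = rng.random() < config.go_background_rate
            if annotated:
                rows.append((gene, term))
    return pd.DataFrame(rows, columns=["gene", "term"])


def write_fasta(sequences: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()]
    SeqIO.write(records, str(path), "fasta")
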