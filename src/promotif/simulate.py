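"""Synthetic study generator with planted ground truth.

Emulates a three-group brain-ischemia expression experiment (sham control,
injury, injury + treatment; 4/3/3 replicates) over a universe of
differentially expressed genes drawn from ten shape-distinct profile
templates — including a "down after injury, restored by treatment" template
and its converse — plus orthologous 3 kb promoter pairs with conserved
blocks and planted PWM consensus sites enriched in the reversal cluster.
Every quantity is recorded in a truth table so each downstream stage can be
verified against planted structure.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as pio
from .clustering import classify_pattern
from .motifs import PWM, PromoterRecord, reverse_complement

#: Profile templates as (control, MCAO, MCAO_NRG1) log2 means. Standardized
#: profiles live on a circle (three values, mean 0, sd 1), so the ten
#: differentially expressed shapes are a "wheel" of angles spread around
#: that circle — exactly one angle falls in the reversal-down zone
#: (injury shift with >= half the shift undone by treatment) and its mirror
#: in the reversal-up zone, which maximizes k-means separability at fixed
#: noise. The last template is the null (unchanged) background that
#: dominates a real transcriptome and keeps the quantile-normalization
#: assumption (most genes unchanged) honest.
DEFAULT_TEMPLATES: tuple[tuple[float, float, float], ...] = (
    (0.0, -2.664, -0.256),  # down after injury, restored by treatment (r=0.90)
    (0.0, 2.664, 0.256),  # up after injury, restored by treatment (r=0.90)
    (0.0, 0.358, 2.706),  # weak injury shift, strong treatment rise
    (0.0, 1.514, 2.939),  # up, treatment pushes further
    (0.0, 2.408, 2.664),  # sustained up
    (0.0, 2.886, 1.929),  # up, partial recovery (r=0.33)
    (0.0, -0.358, -2.706),  # weak injury shift, strong treatment fall
    (0.0, -1.514, -2.939),  # down, treatment pushes further
    (0.0, -2.408, -2.664),  # sustained down
    (0.0, -2.886, -1.929),  # down, partial recovery (r=0.33)
    (0.0, 0.0, 0.0),  # null background
)
#: Template mixing proportions: 79% null background (a transcriptome is
#: mostly unchanged, which quantile normalization relies on); the two
#: reversal templates get 3% and 1.2% of genes so that at the default 3000
#: genes the reversal clusters land near the 92- and 30-gene scale of the
#: motivating three-group stroke study, with a ~600-gene DE universe.
DEFAULT_WEIGHTS: tuple[float, ...] = (0.03, 0.012) + (0.021,) * 8 + (0.79,)

GROUP_SIZES = {"control": 4, "MCAO": 3, "MCAO_NRG1": 3}


@dataclass(frozen=True)
class SimExpressionConfig:
    """Study conditions for the expression matrix."""

    n_genes: int = 3000
    templates: tuple[tuple[float, float, float], ...] = DEFAULT_TEMPLATES
    template_weights: tuple[float, ...] = DEFAULT_WEIGHTS
    replicates_per_group: tuple[int, int, int] = (4, 3, 3)
    noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if len(self.templates) != len(self.template_weights):
            raise ValueError("templates and weights differ in length")
        if abs(sum(self.template_weights) - 1.0) > 1e-9:
            raise ValueError("template weights must sum to 1")
        if any(w < 0 for w in self.template_weights):
            raise ValueError("template weights must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if any(r < 1 for r in self.replicates_per_group):
            raise ValueError("every group needs at least one replicate")
        labels = {classify_pattern(t).label for t in self.templates}
        if not {"reversal_down", "reversal_up"} <= labels:
            raise ValueError(
                "templates must include at least one reversal_down and one "
                "reversal_up profile"
            )


@dataclass(frozen=True)
class SimPromoterConfig:
    """Study conditions for promoter pairs and planted binding sites."""

    promoter_length: int = 3000
    gc_content: float = 0.5
    conserved_block_lengths: tuple[int, ...] = (400, 250, 150)
    ortholog_mutation_rate: float = 0.02
    planted_pwm_ids: tuple[str, ...] = ()
    target_template: int = 0
    site_rate_target_cluster: float = 3.0
    site_rate_background: float = 0.3
    ortholog_missing_fraction: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be positive")
        if not 0 <= self.gc_content <= 1:
            raise ValueError("gc_content must lie in [0, 1]")
        if not 0 <= self.ortholog_mutation_rate <= 1:
            raise ValueError("ortholog_mutation_rate must lie in [0, 1]")
        if not 0 <= self.ortholog_missing_fraction < 1:
            raise ValueError("ortholog_missing_fraction must lie in [0, 1)")
        if self.site_rate_target_cluster < 0 or self.site_rate_background < 0:
            raise ValueError("site rates must be >= 0")
        if sum(self.conserved_block_lengths) > self.promoter_length:
            raise ValueError("conserved blocks exceed the promoter length")
        if any(b < 1 for b in self.conserved_block_lengths):
            raise ValueError("block lengths must be positive")


@dataclass
class TruthGene:
    """Planted truth for one gene."""

    template: int
    ortholog_present: bool = True
    sites: dict[str, list[tuple[int, str]]] = field(default_factory=dict)
    blocks: list[tuple[int, int]] = field(default_factory=list)


class TruthTable(dict):
    """gene id -> TruthGene; every expression-matrix gene appears once."""

    def to_json(self) -> dict:
        return {
            g: {
                "template": t.template,
                "ortholog_present": t.ortholog_present,
                "sites": {m: [[p, s] for p, s in v] for m, v in t.sites.items()},
                "blocks": [list(b) for b in t.blocks],
            }
            for g, t in self.items()
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "TruthTable":
        out = cls()
        for g, d in obj.items():
            out[g] = TruthGene(
                template=int(d["template"]),
                ortholog_present=bool(d["ortholog_present"]),
                sites={
                    m: [(int(p), str(s)) for p, s in v]
                    for m, v in d["sites"].items()
                },
                blocks=[(int(a), int(b)) for a, b in d["blocks"]],
            )
        return out

    def template_labels(self, genes: Sequence[str]) -> np.ndarray:
        return np.array([self[g].template for g in genes])


def simulate_expression(
    cfg: SimExpressionConfig,
) -> tuple[pd.DataFrame, dict[str, str], TruthTable]:
    """Expression matrix, design and truth table for the configured study.

    Gene g's samples are its template's group mean plus N(0, noise_sd^2)
    log2 noise; bitwise deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n_rep = dict(zip(("control", "MCAO", "MCAO_NRG1"), cfg.replicates_per_group))
    genes = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    assignment = rng.choice(
        len(cfg.templates), size=cfg.n_genes, p=np.asarray(cfg.template_weights)
    )
    samples: list[str] = []
    design: dict[str, str] = {}
    means_cols: list[np.ndarray] = []
    templates = np.asarray(cfg.templates)
    for gi, group in enumerate(("control", "MCAO", "MCAO_NRG1")):
        for r in range(n_rep[group]):
            name = f"{group}_{r + 1}"
            samples.append(name)
            design[name] = group
            means_cols.append(templates[assignment, gi])
    values = np.column_stack(means_cols)
    values = values + rng.normal(0.0, cfg.noise_sd, size=values.shape)
    matrix = pd.DataFrame(values, index=genes, columns=samples)
    matrix.index.name = "gene_id"
    truth = TruthTable({g: TruthGene(template=int(t)) for g, t in zip(genes, assignment)})
    return matrix, design, truth


def _random_sequence(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p).astype(np.int8)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _decode(code: np.ndarray) -> str:
    return _BASES[code].tobytes().decode()


def _place_blocks(
    rng: np.random.Generator, lengths: Sequence[int], total: int
) -> list[tuple[int, int]]:
    """Place blocks uniformly at random without overlap (rejection sampling)."""
    for _ in range(1000):
        starts = [int(rng.integers(0, total - L + 1)) for L in lengths]
        intervals = sorted(
            (s, s + L) for s, L in zip(starts, lengths)
        )
        if all(intervals[i][1] <= intervals[i + 1][0] for i in range(len(intervals) - 1)):
            return intervals
    raise RuntimeError("could not place conserved blocks without overlap")


def simulate_promoter_pair(
    gene: str,
    cfg: SimPromoterConfig,
    truth: TruthTable,
    pwms: Mapping[str, PWM],
    gene_index: int,
) -> tuple[PromoterRecord, PromoterRecord | None]:
    """Reference/ortholog promoter pair with planted consensus sites.

    Conserved blocks sit at identical coordinates in both sequences (no
    indel evolution); inside blocks the ortholog differs from the reference
    by i.i.d. substitutions at ``ortholog_mutation_rate``; outside blocks the
    two sequences are independent. Planted sites are exact consensus (or
    reverse-complement) occurrences of the named PWMs, fully inside blocks,
    mutually non-overlapping, written into both sequences and recorded in
    the truth table. Deterministic given (cfg.seed, gene_index).
    """
    entry = truth[gene]
    for mid in cfg.planted_pwm_ids:
        if mid not in pwms:
            raise ValueError(f"planted PWM {mid!r} not in the matrix set")
        if len(pwms[mid]) > cfg.promoter_length:
            raise ValueError(f"promoter shorter than matrix {mid!r}")
    rng = np.random.default_rng([cfg.seed, gene_index])
    L = cfg.promoter_length
    ref = _random_sequence(rng, L, cfg.gc_content)
    orth = _random_sequence(rng, L, cfg.gc_content)
    blocks = _place_blocks(rng, cfg.conserved_block_lengths, L)
    entry.blocks = list(blocks)
    for s, e in blocks:
        seg = ref[s:e].copy()
        mut = rng.random(e - s) < cfg.ortholog_mutation_rate
        if mut.any():
            shift = rng.integers(1, 4, size=int(mut.sum())).astype(np.int8)
            seg[mut] = (seg[mut] + shift) % 4
        orth[s:e] = seg

    entry.ortholog_present = bool(rng.random() >= cfg.ortholog_missing_fraction)

    occupied: list[tuple[int, int]] = []
    entry.sites = {}
    enriched = cfg.planted_pwm_ids[0] if cfg.planted_pwm_ids else None
    for mid in cfg.planted_pwm_ids:
        pwm = pwms[mid]
        site_len = len(pwm)
        if all(e - s < site_len for s, e in blocks):
            raise ValueError(
                f"planted site for {mid!r} ({site_len} bp) is longer than every "
                "conserved block"
            )
        rate = (
            cfg.site_rate_target_cluster
            if (mid == enriched and entry.template == cfg.target_template)
            else cfg.site_rate_background
        )
        n_sites = int(rng.poisson(rate))
        placed: list[tuple[int, str]] = []
        for _ in range(n_sites):
            for _attempt in range(200):
                bs, be = blocks[int(rng.integers(len(blocks)))]
                if be - bs < site_len:
                    continue
                pos = int(rng.integers(bs, be - site_len + 1))
                if any(pos < oe and pos + site_len > os for os, oe in occupied):
                    continue
                strand = "+" if rng.random() < 0.5 else "-"
                seq = pwm.consensus if strand == "+" else reverse_complement(pwm.consensus)
                site_code = np.array(
                    ["ACGT".index(c) for c in seq], dtype=np.int8
                )
                ref[pos : pos + site_len] = site_code
                orth[pos : pos + site_len] = site_code
                occupied.append((pos, pos + site_len))
                placed.append((pos, strand))
                break
        if placed:
            entry.sites[mid] = sorted(placed)
    ref_rec = PromoterRecord(gene_id=gene, species="rat", sequence=_decode(ref))
    if not entry.ortholog_present:
        return ref_rec, None
    orth_rec = PromoterRecord(gene_id=gene, species="mouse", sequence=_decode(orth))
    return ref_rec, orth_rec


def make_pwm_set(
    n_matrices: int = 6,
    lengths: Sequence[int] | None = None,
    seed: int = 7,
    consensus_count: int = 17,
    other_count: int = 1,
) -> list[PWM]:
    """A deterministic set of sharply peaked synthetic TRANSFAC matrices.

    Each position holds ``consensus_count`` observations of a random
    consensus base and ``other_count`` of each alternative, giving strong
    but not degenerate positions so near-consensus windows can still pass
    the 0.85/0.95 MATCH cutoffs.
    """
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = [8 + int(rng.integers(0, 5)) for _ in range(n_matrices)]
    pwms = []
    for i, L in enumerate(lengths):
        consensus = rng.integers(0, 4, size=L)
        counts = np.full((L, 4), float(other_count))
        counts[np.arange(L), consensus] = float(consensus_count)
        pwms.append(PWM(id=f"M{i + 1:02d}", counts=counts))
    return pwms


@dataclass
class StudyBundle:
    """In-memory synthetic study plus the files it was written to."""

    expression: pd.DataFrame
    design: dict[str, str]
    orthologs: dict[str, str | None]
    ref_promoters: dict[str, PromoterRecord]
    orth_promoters: dict[str, PromoterRecord]
    pwms: list[PWM]
    truth: TruthTable
    paths: dict[str, Path]


def simulate_study(
    expr_cfg: SimExpressionConfig,
    prom_cfg: SimPromoterConfig,
    pwms: Sequence[PWM],
    out_dir: str | Path,
) -> StudyBundle:
    """Generate and write a complete synthetic study to ``out_dir``.

    Writes expression/design/ortholog TSVs, reference and ortholog promoter
    FASTAs, the TRANSFAC matrix file and the truth JSON; all files
    round-trip losslessly through the package parsers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pwm_map = {p.id: p for p in pwms}
    prom_cfg = dataclasses.replace(
        prom_cfg,
        planted_pwm_ids=prom_cfg.planted_pwm_ids or tuple(pwm_map),
    )
    matrix, design, truth = simulate_expression(expr_cfg)
    ref_promoters: dict[str, PromoterRecord] = {}
    orth_promoters: dict[str, PromoterRecord] = {}
    orthologs: dict[str, str | None] = {}
    for gi, gene in enumerate(matrix.index):
        ref, orth = simulate_promoter_pair(gene, prom_cfg, truth, pwm_map, gi)
        ref_promoters[gene] = ref
        if orth is not None:
            orth_promoters[gene] = orth
            orthologs[gene] = f"m_{gene}"
        else:
            orthologs[gene] = None

    paths = {
        "expression": out / "expression.tsv",
        "design": out / "design.tsv",
        "orthologs": out / "orthologs.tsv",
        "ref_fasta": out / "promoters_rat.fasta",
        "orth_fasta": out / "promoters_mouse.fasta",
        "matrices": out / "matrices.transfac",
        "truth": out / "truth.json",
    }
    pio.write_expression_tsv(matrix, paths["expression"])
    pio.write_design_tsv(design, paths["design"])
    pio.write_ortholog_tsv(orthologs, paths["orthologs"])
    pio.write_promoter_fasta(list(ref_promoters.values()), paths["ref_fasta"])
    pio.write_promoter_fasta(list(orth_promoters.values()), paths["orth_fasta"])
    pio.write_transfac_file(list(pwms), paths["matrices"])
    pio.write_json(truth.to_json(), paths["truth"])
    # round-trip note: expression values are written at 6 decimals; reload the
    # written matrix so the in-memory bundle is bit-identical to the files
    matrix = pio.read_expression_tsv(paths["expression"])
    return StudyBundle(
        expression=matrix,
        design=design,
        orthologs=orthologs,
        ref_promoters=ref_promoters,
        orth_promoters=orth_promoters,
        pwms=list(pwms),
        truth=truth,
        paths=paths,
    )
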