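"""Synthetic inputs with known ground truth for the RIP-Seq pipeline.

Four generators emulate the statistical structure the analysis assumes:

* negative-binomial RIP-Seq count matrices (variance mu + phi*mu^2) with
  library-size variation, a per-gene IP pulldown background shared across
  conditions, and an IP-specific enrichment effect injected multiplicatively
  into the wild-type IP samples of a planted transcript subset — so the
  double-difference contrast is the estimand by construction;
* AU-rich 3'UTR sequences with exact target composition, optionally planted
  AUUUA pentamers, polyU stretches and a fixed region, with every planted
  feature recorded;
* a random interaction network with a pathway optionally over-wired to a
  query gene set;
* knockdown/control expression with planted fold changes concordant with the
  RIP truth table.

Every generator is deterministic under a fixed seed; one global seed expands
to independent per-stage child streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .enrichment import CountMatrix

U_STRETCH_LEN = 17
_PENTAMER = "AUUUA"


# ---------------------------------------------------------------------------
# RIP-Seq counts


@dataclass
class RipSimConfig:
    """Study-shaped RIP-Seq simulation: triplicate IP/input libraries per
    condition, a planted enriched subset, shared NB dispersion."""

    n_genes: int = 1000
    n_enriched: int = 50
    enrichment_log2fc: float = 2.0
    dispersion: float = 0.05  # NB dispersion phi; variance = mu + phi*mu^2
    lib_sizes: tuple[float, ...] | None = None  # expected totals, one per sample
    mean_lib_size: float = 15_000_000.0  # study-scale sequencing depth
    lib_size_cv: float = 0.15  # uniform jitter half-width as a fraction
    baseline_logmean_range: tuple[float, float] = (0.0, 9.0)  # log2 CPM
    ip_background_sd: float = 0.5  # per-gene log2 IP/input pulldown ratio
    include_wmut: bool = False
    cell_line: str = "SIM"
    n_replicates: int = 3
    frac_up: float = 0.88  # regulation direction split among enriched genes
    seed: int = 0

    @property
    def conditions(self) -> tuple[str, ...]:
        return ("C", "W", "Wmut") if self.include_wmut else ("C", "W")

    def validate(self) -> None:
        if self.n_enriched > self.n_genes:
            raise ValueError("n_enriched exceeds n_genes")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.lib_sizes is not None and any(l <= 0 for l in self.lib_sizes):
            raise ValueError("library sizes must be positive")
        if self.n_replicates < 1:
            raise ValueError("need at least 1 replicate")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _sample_name(cell_line: str, condition: str, fraction: str, rep: int) -> str:
    return f"{cell_line}_{condition}_{fraction}_{rep}"


def simulate_ripseq_counts(cfg: RipSimConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a count matrix plus its truth table.

    Returns (CountMatrix, truth) where truth is indexed by gene with columns
    ``is_enriched``, ``true_log2fc`` and ``regulation_direction``. At
    dispersion 0 the counts are the rounded expected means (no sampling), so
    zero-effect configurations give exactly equal group means per gene.
    """
    cfg.validate()
    rng_mean, rng_count, rng_lib, rng_dir = _child_rngs(cfg.seed, 4)

    genes = [f"g{i:05d}" for i in range(cfg.n_genes)]
    design_rows = []
    for cond in cfg.conditions:
        for frac in ("input", "IP"):
            for rep in range(1, cfg.n_replicates + 1):
                design_rows.append(
                    {
                        "sample": _sample_name(cfg.cell_line, cond, frac, rep),
                        "cell_line": cfg.cell_line,
                        "condition": cond,
                        "fraction": frac,
                        "replicate": rep,
                    }
                )
    design = pd.DataFrame(design_rows)
    n_samples = len(design)

    if cfg.lib_sizes is not None:
        if len(cfg.lib_sizes) != n_samples:
            raise ValueError(
                f"lib_sizes has {len(cfg.lib_sizes)} entries; design has {n_samples} samples"
            )
        libs = np.asarray(cfg.lib_sizes, dtype=float)
    else:
        jitter = rng_lib.uniform(1 - cfg.lib_size_cv, 1 + cfg.lib_size_cv, n_samples)
        libs = cfg.mean_lib_size * jitter

    lo, hi = cfg.baseline_logmean_range
    base_logcpm = rng_mean.uniform(lo, hi, cfg.n_genes)
    ip_shift = rng_mean.normal(0.0, cfg.ip_background_sd, cfg.n_genes)
    enriched_idx = np.arange(cfg.n_enriched)
    is_enriched = np.zeros(cfg.n_genes, dtype=bool)
    is_enriched[enriched_idx] = True

    counts = np.zeros((cfg.n_genes, n_samples), dtype=np.int64)
    for j, row in design.iterrows():
        logcpm = base_logcpm.copy()
        if row["fraction"] == "IP":
            logcpm = logcpm + ip_shift
            if row["condition"] == "W":
                logcpm = logcpm + np.where(is_enriched, cfg.enrichment_log2fc, 0.0)
        mu = 2.0**logcpm / 1e6 * libs[j]
        if cfg.dispersion == 0:
            counts[:, j] = np.rint(mu).astype(np.int64)
        else:
            n_nb = 1.0 / cfg.dispersion
            p_nb = n_nb / (n_nb + mu)
            counts[:, j] = rng_count.negative_binomial(n_nb, p_nb)

    direction = np.array(["none"] * cfg.n_genes, dtype=object)
    if cfg.n_enriched:
        up = rng_dir.random(cfg.n_enriched) < cfg.frac_up
        direction[enriched_idx] = np.where(up, "up", "down")

    truth = pd.DataFrame(
        {
            "is_enriched": is_enriched,
            "true_log2fc": np.where(is_enriched, cfg.enrichment_log2fc, 0.0),
            "regulation_direction": direction,
        },
        index=pd.Index(genes, name="gene"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=design["sample"].tolist()),
        design=design,
        lib_size=pd.Series(libs, index=design["sample"].tolist()),
    )
    return cm, truth


# ---------------------------------------------------------------------------
# 3'UTR sequences


@dataclass
class UtrSimConfig:
    """AU-rich UTR backbone at an exact target composition, with planted
    pentamers, polyU stretches and an optional fixed region."""

    n_sequences: int = 286
    length_range: tuple[int, int] = (425, 1994)
    gc_target: float = 0.33
    pentamer_rate: float = 1.0  # expected planted AUUUA per kb
    u_stretch_prob: float = 0.07
    u_stretch_len: int = U_STRETCH_LEN
    pentamer_prevalence: float | None = None  # exact fraction of sequences
    # with >= 1 pentamer; chance occurrences are destroyed when set
    planted_region: str | None = None
    planted_region_fraction: float = 1.0
    id_prefix: str = "utr"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.gc_target <= 1.0:
            raise ValueError("gc_target must lie in [0, 1]")
        if self.length_range[0] > self.length_range[1] or self.length_range[0] < 1:
            raise ValueError("invalid length range")
        if self.u_stretch_prob > 0 and self.u_stretch_len > self.length_range[0]:
            raise ValueError("U-stretch longer than the shortest sequence")
        if self.planted_region and len(self.planted_region) > self.length_range[0]:
            raise ValueError("planted region longer than the shortest sequence")


def _exact_composition_backbone(length: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    n_g = int(round(length * gc / 2.0))
    n_c = int(round(length * gc)) - n_g
    n_a = (length - n_g - n_c) // 2
    n_u = length - n_g - n_c - n_a
    letters = np.array(
        ["G"] * n_g + ["C"] * n_c + ["A"] * n_a + ["U"] * n_u, dtype="<U1"
    )
    rng.shuffle(letters)
    return letters


def _destroy_pentamers(arr: np.ndarray, rng: np.random.Generator) -> None:
    """Flip the middle base of every AUUUA occurrence until none remain."""
    s = "".join(arr)
    while True:
        i = s.find(_PENTAMER)
        if i < 0:
            return
        arr[i + 2] = rng.choice(["C", "G"])
        s = "".join(arr)


def _place(
    occupied: list[tuple[int, int]], length: int, span: int, rng: np.random.Generator
) -> int | None:
    """Random start for a span avoiding occupied intervals; None if no room."""
    for _ in range(200):
        start = int(rng.integers(0, length - span + 1))
        if all(start + span <= a or start >= b for a, b in occupied):
            occupied.append((start, start + span))
            return start
    return None


def simulate_utrs(cfg: UtrSimConfig) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate UTR FASTA records plus a truth table of planted features.

    Returns (records, truth): records are (id, sequence) pairs over
    {A,C,G,U}; truth is indexed by sequence id with columns
    ``n_planted_pentamers``, ``planted_u_stretch``, ``has_planted_region``
    and ``length``. Planted motifs overwrite the backbone (length is
    preserved) at non-overlapping positions, so every planted feature is
    recoverable by a direct scan.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range

    n = cfg.n_sequences
    if cfg.pentamer_prevalence is not None:
        n_with = int(round(cfg.pentamer_prevalence * n))
        with_pentamer = np.zeros(n, dtype=bool)
        with_pentamer[rng.choice(n, n_with, replace=False)] = True
    else:
        with_pentamer = None

    if cfg.planted_region:
        n_region = int(round(cfg.planted_region_fraction * n))
        region_subset = np.zeros(n, dtype=bool)
        region_subset[rng.choice(n, n_region, replace=False)] = True
    else:
        region_subset = np.zeros(n, dtype=bool)

    records: list[tuple[str, str]] = []
    rows = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        arr = _exact_composition_backbone(length, cfg.gc_target, rng)
        if with_pentamer is not None:
            _destroy_pentamers(arr, rng)
        occupied: list[tuple[int, int]] = []

        has_region = bool(region_subset[i])
        if has_region:
            region = cfg.planted_region.upper().replace("T", "U")
            start = _place(occupied, length, len(region), rng)
            if start is None:
                has_region = False
            else:
                arr[start : start + len(region)] = list(region)

        planted_stretch = False
        if rng.random() < cfg.u_stretch_prob:
            start = _place(occupied, length, cfg.u_stretch_len, rng)
            if start is not None:
                arr[start : start + cfg.u_stretch_len] = "U"
                planted_stretch = True

        if with_pentamer is not None:
            n_pent = 1 + rng.poisson(0.5) if with_pentamer[i] else 0
        else:
            n_pent = rng.poisson(cfg.pentamer_rate * length / 1000.0)
        planted_pent = 0
        for _ in range(n_pent):
            start = _place(occupied, length, len(_PENTAMER), rng)
            if start is not None:
                arr[start : start + len(_PENTAMER)] = list(_PENTAMER)
                planted_pent += 1

        seq = "".join(arr)
        sid = f"{cfg.id_prefix}{i:04d}"
        records.append((sid, seq))
        rows.append(
            {
                "id": sid,
                "length": length,
                "n_planted_pentamers": planted_pent,
                "planted_u_stretch": planted_stretch,
                "has_planted_region": has_region,
            }
        )
    truth = pd.DataFrame(rows).set_index("id")
    return records, truth


# ---------------------------------------------------------------------------
# Interaction network


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __len__(self) -> int:
        return len(self.genes)


def simulate_network(
    n_nodes: int = 500,
    n_edges: int = 5000,
    pathway_size: int = 40,
    ags_size: int = 40,
    planted_connectivity: float = 0.0,
    seed: int = 0,
    ags_nodes: list[str] | None = None,
) -> tuple[nx.Graph, GeneSet, GeneSet]:
    """Random interaction network with an optionally over-wired pathway.

    A simple undirected G(n, m) graph is drawn with uniform confidence
    scores in [0.5, 1]; a pathway set and a disjoint query (AGS) set are
    sampled (or the AGS is supplied as existing node ids via ``ags_nodes``).
    With ``planted_connectivity`` = c > 0, approximately c times the random
    expectation of AGS-pathway crossing edges are added on top of the
    background wiring.
    """
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise ValueError(f"{n_edges} edges infeasible for {n_nodes} nodes")
    if ags_nodes is None and pathway_size + ags_size > n_nodes:
        raise ValueError("pathway and AGS sizes exceed node count")
    rng = np.random.default_rng(seed)
    g = nx.gnm_random_graph(n_nodes, n_edges, seed=int(rng.integers(2**31)))
    mapping = {i: f"g{i:05d}" for i in g.nodes}
    g = nx.relabel_nodes(g, mapping)
    for u, v in g.edges:
        g.edges[u, v]["confidence"] = float(rng.uniform(0.5, 1.0))

    nodes = sorted(g.nodes)
    if ags_nodes is not None:
        unknown = set(ags_nodes) - set(nodes)
        if unknown:
            raise ValueError(f"AGS nodes absent from the network: {sorted(unknown)[:5]}")
        ags_nodes = sorted(ags_nodes)
        ags_size = len(ags_nodes)
        pool = [x for x in nodes if x not in set(ags_nodes)]
        picked = rng.choice(len(pool), pathway_size, replace=False)
        pathway_nodes = [pool[i] for i in picked]
    else:
        picked = rng.choice(len(nodes), pathway_size + ags_size, replace=False)
        pathway_nodes = [nodes[i] for i in picked[:pathway_size]]
        ags_nodes = [nodes[i] for i in picked[pathway_size:]]

    if planted_connectivity > 0:
        density = n_edges / max_edges
        expected = pathway_size * ags_size * density
        n_extra = int(round(planted_connectivity * expected))
        added = attempts = 0
        max_attempts = 1000 * max(n_extra, 1)
        while added < n_extra:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"cannot place {n_extra} extra cross edges between sets of "
                    f"{ags_size} and {pathway_size} nodes"
                )
            u = ags_nodes[int(rng.integers(ags_size))]
            v = pathway_nodes[int(rng.integers(pathway_size))]
            if u != v and not g.has_edge(u, v):
                g.add_edge(u, v, confidence=float(rng.uniform(0.5, 1.0)))
                added += 1

    return (
        g,
        GeneSet("pathway", frozenset(pathway_nodes)),
        GeneSet("ags", frozenset(ags_nodes)),
    )


# ---------------------------------------------------------------------------
# Knockdown expression


def simulate_knockdown(
    truth: pd.DataFrame,
    fc_up: float = 5.0,
    fc_down: float = 5.0,
    noise_sd: float = 0.0,
    n_replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired knockdown/control expression concordant with the RIP truth.

    Genes with ``regulation_direction`` "up" get knockdown/control ratio
    fc_up per replicate (times multiplicative log-normal noise with sigma
    ``noise_sd`` on the natural-log scale), "down" genes get 1/fc_down, the
    rest ratio 1. Returns a DataFrame with columns kd_1..n, ctrl_1..n.
    """
    if fc_up <= 1 or fc_down <= 1:
        raise ValueError("fold changes must exceed 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    n = len(truth)
    base = np.exp(rng.normal(np.log(500.0), 1.0, n))
    ratio = np.select(
        [truth["regulation_direction"].values == "up",
         truth["regulation_direction"].values == "down"],
        [fc_up, 1.0 / fc_down],
        default=1.0,
    )
    data = {}
    for r in range(1, n_replicates + 1):
        ctrl_noise = np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd else 1.0
        kd_noise = np.exp(rng.normal(0.0, noise_sd, n)) if noise_sd else 1.0
        data[f"ctrl_{r}"] = base * ctrl_noise
        data[f"kd_{r}"] = base * ratio * kd_noise
    cols = [f"kd_{r}" for r in range(1, n_replicates + 1)] + [
        f"ctrl_{r}" for r in range(1, n_replicates + 1)
    ]
    return pd.DataFrame(data, index=truth.index)[cols]
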