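"""Synthetic pan-cancer multi-omics cohort generator with planted truth.

Emulates the structure the marker/regulator pipeline consumes: a cohort
partitioned into tumor types and subtypes grouped into meta-clusters;
matrisome genes with subtype-specific bimodal over-expression; stacked
regulator layers (TF expression, gene-program scores, miRNA expression,
gene-level methylation, copy-number, binary mutations, stromal fraction)
with planted regulator->gene effects; and exponential survival times whose
hazard depends on planted prognostic genes.

Planted marker shift
--------------------
A marker gene is bimodal: background samples follow N(mu_g, sigma^2) while
the marked subtype follows N(mu_g + delta, noise model).  The effect size
``marker_effect_sd`` is expressed in cohort-SD units: delta is chosen so
the marked subtype sits ``e`` marginal-cohort standard deviations above
the background mean, solving the self-consistency
``delta = e * sigma / sqrt(1 - f(1-f) e^2)`` where ``f`` is the marked
fraction of the cohort (the shift itself inflates the cohort SD).  The
denominator is floored at 0.25 so the shift stays finite for large
``f * e`` combinations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import load_catalog
from .regulators import RegulatorLayers, GENE_INDEXED_LAYERS

__all__ = ["CohortConfig", "PlantedTruth", "Cohort", "generate_cohort",
           "write_cohort", "read_cohort"]

#: layers whose regulators are free-standing entities (not gene-indexed)
FREE_LAYERS = ("tf", "program", "mirna")


@dataclass
class CohortConfig:
    """Knobs of the synthetic cohort; defaults are the benchmark conditions.

    Five tumor types, two subtypes each (ten subtypes in five
    meta-clusters), 50 patients per subtype, a 3 cohort-SD marker effect
    and a unit standardized regulator slope.
    """

    n_types: int = 5
    subtypes_per_type: int = 2
    n_samples_per_subtype: int = 50
    n_matrisome_genes: int = 120
    n_regulators_per_layer: dict = field(
        default_factory=lambda: {"tf": 10, "program": 8, "mirna": 10}
    )
    n_planted_markers_per_subtype: int = 5
    n_links_per_marker: int = 2
    planted_link_layers: tuple = ("tf", "program", "cna", "methylation")
    n_prognostic_per_subtype: int = 1
    marker_effect_sd: float = 3.0
    regulator_effect: float = 1.0
    noise_sd: float = 0.5
    base_mean: float = 8.0
    base_sd: float = 2.0
    n_metaclusters: int = 5
    metacluster_shift_sd: float = 2.0
    metacluster_gene_frac: float = 0.10
    censoring_rate: float = 0.3
    hazard_log_hr: float = 1.0
    base_hazard: float = 1.0 / 1000.0  # events per day
    mutation_rate: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_types": self.n_types,
            "subtypes_per_type": self.subtypes_per_type,
            "n_samples_per_subtype": self.n_samples_per_subtype,
            "n_matrisome_genes": self.n_matrisome_genes,
            "n_metaclusters": self.n_metaclusters,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1, got {v}")
        if self.marker_effect_sd < 0:
            raise ValueError("marker_effect_sd must be >= 0")
        if not (0 <= self.censoring_rate < 1):
            raise ValueError("censoring_rate must be in [0, 1)")
        n_subtypes = self.n_types * self.subtypes_per_type
        need = n_subtypes * self.n_planted_markers_per_subtype
        if need > self.n_matrisome_genes:
            raise ValueError(
                f"planted markers ({need}) exceed gene count "
                f"({self.n_matrisome_genes})"
            )
        for layer in self.planted_link_layers:
            if layer in FREE_LAYERS:
                if self.n_regulators_per_layer.get(layer, 0) < 1:
                    raise ValueError(
                        f"planted links on layer {layer!r} but the layer "
                        "has no regulators"
                    )
        if self.n_links_per_marker > len(self.planted_link_layers):
            raise ValueError(
                "n_links_per_marker exceeds the number of planted link layers"
            )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by the generator.

    markers: set of (subtype, gene)
    links: set of (subtype, gene, regulator, layer, effect)
    prognostic: set of (subtype, gene, sign)
    """

    markers: frozenset
    links: frozenset
    prognostic: frozenset

    def __post_init__(self):
        mk = {(s, g) for s, g in self.markers}
        for s, g, *_ in self.links:
            if (s, g) not in mk:
                raise ValueError(f"link on non-marker pair {(s, g)}")

    def link_pairs(self) -> set:
        """Planted links keyed as (subtype, gene, layer, regulator)."""
        return {(s, g, layer, r) for s, g, r, layer, _ in self.links}

    def to_json(self) -> str:
        return json.dumps(
            {
                "markers": sorted(map(list, self.markers)),
                "links": sorted(map(list, self.links)),
                "prognostic": sorted(map(list, self.prognostic)),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        return cls(
            markers=frozenset(tuple(x) for x in d["markers"]),
            links=frozenset(tuple(x) for x in d["links"]),
            prognostic=frozenset(tuple(x) for x in d["prognostic"]),
        )


@dataclass
class Cohort:
    expression: pd.DataFrame  # genes x samples, log-scale, non-negative
    annotation: pd.DataFrame  # indexed by sample
    layers: RegulatorLayers
    truth: PlantedTruth
    config: CohortConfig | None = None


def _marker_shift(e: float, f: float, sigma: float) -> float:
    denom = max(1.0 - f * (1.0 - f) * e * e, 0.25)
    return e * sigma / np.sqrt(denom)


def generate_cohort(config: CohortConfig) -> Cohort:
    """Draw a full synthetic cohort; a fixed seed is byte-identical."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cat = load_catalog()

    n_sub = config.n_types * config.subtypes_per_type
    n_per = config.n_samples_per_subtype
    n_samples = n_sub * n_per
    n_genes = config.n_matrisome_genes

    genes = list(rng.choice(np.asarray(cat.genes), size=n_genes, replace=False))
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]

    subtypes, types, clusters = [], [], []
    for t in range(config.n_types):
        mc = t % config.n_metaclusters
        for s in range(config.subtypes_per_type):
            subtypes.append(f"T{t + 1}.{chr(ord('a') + s)}")
            types.append(f"T{t + 1}")
            clusters.append(f"MC{mc + 1}")
    sub_of_sample = np.repeat(subtypes, n_per)
    type_of_sample = np.repeat(types, n_per)
    cluster_of_sample = np.repeat(clusters, n_per)

    purity = rng.uniform(0.4, 0.9, size=n_samples)
    age = np.clip(rng.normal(60, 10, size=n_samples), 30, 90)

    # background expression: per-gene mean jittered around base_mean
    mu = config.base_mean + rng.normal(0, 1, size=n_genes)
    sigma = config.base_sd
    expr = mu[:, None] + rng.normal(0, sigma, size=(n_genes, n_samples))

    # planted markers: disjoint across subtypes, excluded from cluster-shift
    marker_pool = rng.permutation(n_genes)
    markers: dict[str, list[int]] = {}
    k = 0
    for st in subtypes:
        markers[st] = list(
            marker_pool[k : k + config.n_planted_markers_per_subtype]
        )
        k += config.n_planted_markers_per_subtype
    marker_idx = set(marker_pool[:k])

    # meta-cluster structure: shared mean shift on a random slice of the
    # non-marker genes for each meta-cluster
    n_shift = int(round(config.metacluster_gene_frac * n_genes))
    free = np.array([i for i in range(n_genes) if i not in marker_idx])
    for mc in sorted(set(clusters)):
        if n_shift == 0 or len(free) == 0:
            break
        shift_genes = rng.choice(free, size=min(n_shift, len(free)), replace=False)
        cols = cluster_of_sample == mc
        expr[np.ix_(shift_genes, cols)] += config.metacluster_shift_sd * sigma

    # regulator layers
    layer_frames: dict[str, pd.DataFrame] = {}
    for layer in FREE_LAYERS:
        n_reg = config.n_regulators_per_layer.get(layer, 0)
        if n_reg > 0:
            ids = [f"{layer.upper()}{i + 1:03d}" for i in range(n_reg)]
            layer_frames[layer] = pd.DataFrame(
                rng.normal(0, 1, size=(n_reg, n_samples)),
                index=ids, columns=samples,
            )
    cna_levels = np.array([-2, -1, 0, 1, 2])
    cna_probs = np.array([0.03, 0.12, 0.70, 0.12, 0.03])
    layer_frames["cna"] = pd.DataFrame(
        rng.choice(cna_levels, p=cna_probs, size=(n_genes, n_samples)).astype(float),
        index=genes, columns=samples,
    )
    layer_frames["methylation"] = pd.DataFrame(
        rng.beta(2, 2, size=(n_genes, n_samples)),
        index=genes, columns=samples,
    )
    layer_frames["mutation"] = pd.DataFrame(
        rng.binomial(1, config.mutation_rate, size=(n_genes, n_samples)).astype(float),
        index=genes, columns=samples,
    )
    layer_frames["stromal"] = pd.DataFrame(
        (1.0 - purity)[None, :], index=["stromal_fraction"], columns=samples
    )

    def _reg_values_std(layer: str, reg: str) -> np.ndarray:
        """Standardized regulator values on the generative scale."""
        v = layer_frames[layer].loc[reg].to_numpy(float)
        if layer in FREE_LAYERS:
            return v
        if layer == "cna":
            sd = np.sqrt((cna_levels**2 * cna_probs).sum())
            return v / sd
        if layer == "methylation":  # Beta(2,2): mean .5, var 1/20
            return (v - 0.5) / np.sqrt(1 / 20)
        if layer == "mutation":
            p = config.mutation_rate
            return (v - p) / np.sqrt(p * (1 - p))
        return (v - v.mean()) / (v.std() or 1.0)

    # plant marker shifts and regulator links
    f = n_per / n_samples
    delta = _marker_shift(config.marker_effect_sd, f, sigma)
    links = set()
    link_layer_cycle = list(config.planted_link_layers)
    gene_arr = np.array(genes)
    for si, st in enumerate(subtypes):
        cols = sub_of_sample == st
        for mi, gi in enumerate(markers[st]):
            g = gene_arr[gi]
            signal = np.zeros(cols.sum())
            chosen_layers = [
                link_layer_cycle[(mi + j) % len(link_layer_cycle)]
                for j in range(config.n_links_per_marker)
            ]
            for layer in chosen_layers:
                if layer in FREE_LAYERS:
                    reg = str(rng.choice(layer_frames[layer].index))
                else:
                    reg = g  # cis effect: the gene's own row
                z = _reg_values_std(layer, reg)[cols]
                signal += config.regulator_effect * z
                links.add((st, g, reg, layer, config.regulator_effect))
            expr[gi, cols] = (
                mu[gi] + delta + signal
                + rng.normal(0, config.noise_sd, size=cols.sum())
            )

    expr = np.clip(expr, 0.0, None)
    expression = pd.DataFrame(
        expr, index=pd.Index(genes, name="gene"), columns=samples
    )
    for frame in layer_frames.values():
        frame.index.name = "regulator"

    # survival: exponential hazard scaled by the subtype's prognostic gene
    prognostic = set()
    log_risk = np.zeros(n_samples)
    for st in subtypes:
        cols = sub_of_sample == st
        prog_genes = markers[st][: config.n_prognostic_per_subtype]
        for gi in prog_genes:
            g = gene_arr[gi]
            v = expr[gi, cols]
            z = (v - v.mean()) / (v.std() or 1.0)
            log_risk[cols] += config.hazard_log_hr * z
            prognostic.add((st, g, 1))
    haz = config.base_hazard * np.exp(log_risk)
    t_event = rng.exponential(1.0 / haz)
    r = config.censoring_rate
    if r > 0:
        cens_rate = haz * r / (1.0 - r)
        t_cens = rng.exponential(1.0 / cens_rate)
    else:
        t_cens = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-3)

    annotation = pd.DataFrame(
        {
            "tumor_type": type_of_sample,
            "subtype": sub_of_sample,
            "meta_cluster": cluster_of_sample,
            "purity": purity,
            "age": age,
            "time": time,
            "event": event,
        },
        index=pd.Index(samples, name="sample"),
    )

    truth = PlantedTruth(
        markers=frozenset((st, gene_arr[gi]) for st in subtypes for gi in markers[st]),
        links=frozenset(links),
        prognostic=frozenset(prognostic),
    )
    return Cohort(expression, annotation, RegulatorLayers(layer_frames), truth, config)


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write TSVs (expression, annotation, one per layer) plus truth JSON."""
    if cohort.expression.shape[1] == 0:
        raise ValueError("refusing to write a cohort with 0 samples")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    try:
        p = directory / "expression.tsv"
        cohort.expression.to_csv(p, sep="\t", index_label="gene")
        paths["expression"] = p
        p = directory / "annotation.tsv"
        cohort.annotation.to_csv(p, sep="\t")
        paths["annotation"] = p
        for name, frame in cohort.layers.layers.items():
            p = directory / f"layer_{name}.tsv"
            frame.to_csv(p, sep="\t", index_label="regulator")
            paths[f"layer_{name}"] = p
        p = directory / "truth.json"
        p.write_text(cohort.truth.to_json())
        paths["truth"] = p
    except OSError as exc:
        raise OSError(f"failed writing cohort under {directory}: {exc}") from exc
    return paths


def read_cohort(directory: str | Path) -> Cohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    expression = pd.read_csv(directory / "expression.tsv", sep="\t", index_col=0)
    annotation = pd.read_csv(directory / "annotation.tsv", sep="\t", index_col=0)
    frames = {}
    for p in sorted(directory.glob("layer_*.tsv")):
        name = p.stem[len("layer_"):]
        frames[name] = pd.read_csv(p, sep="\t", index_col=0)
    truth = PlantedTruth.from_json((directory / "truth.json").read_text())
    return Cohort(expression, annotation, RegulatorLayers(frames), truth)
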