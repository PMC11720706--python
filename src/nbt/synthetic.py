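"""Synthetic cohorts and networks with planted ground truth.

Three generators emulate the data the pipeline consumes, each with a known
truth object for testing recovery:

* a scale-free (preferential-attachment) PPI graph carrying a densely wired
  planted module in which anchors and signature genes live;
* an immunotherapy cohort whose planted anchor genes vary linearly with a
  uniform 4-level response grade on top of Gaussian noise;
* a survival cohort whose event times follow an exponential proportional-
  hazards law over a planted signature, with independent exponential
  censoring.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .anchor import ResponseGrades
from .exceptions import ValidationError
from .io import ClinicalTable, ExpressionMatrix

import pandas as pd

__all__ = ["SyntheticTruth", "simulate_ppi", "simulate_immunotherapy_cohort",
           "simulate_survival_cohort", "simulate_benchmark", "GRADE_TO_LABEL"]

GRADE_TO_LABEL = {1: "PD", 2: "SD", 3: "PR", 4: "CR"}


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic dataset."""

    seed: int
    anchors: list[str] = field(default_factory=list)
    module: list[str] = field(default_factory=list)
    signature_genes: list[str] = field(default_factory=list)
    beta: list[float] = field(default_factory=list)
    noise_genes: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "anchors": self.anchors, "module": self.module,
                "signature_genes": self.signature_genes, "beta": self.beta,
                "params": self.params}


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def simulate_ppi(n_genes: int = 300, attachment_m: int = 2, module_size: int = 10,
                 seed: int = 0) -> tuple[nx.Graph, SyntheticTruth]:
    """Preferential-attachment PPI graph with a planted clique module.

    Edge confidence scores are drawn uniformly in [700, 999] so every edge
    survives the high-confidence cutoff. The planted module is a clique over
    ``module_size`` randomly chosen nodes; truth records its members.
    """
    if n_genes < module_size + attachment_m:
        raise ValidationError("n_genes must be at least module_size + attachment_m")
    rng = np.random.default_rng(seed)
    base = nx.barabasi_albert_graph(n_genes, attachment_m,
                                    seed=int(rng.integers(2**31)))
    ba_edges = base.number_of_edges()
    names = _gene_names(n_genes)
    g = nx.relabel_nodes(base, dict(enumerate(names)))
    module = sorted(rng.choice(names, size=module_size, replace=False).tolist())
    for i, a in enumerate(module):
        for b in module[i + 1:]:
            g.add_edge(a, b)
    for a, b in g.edges:
        g[a][b]["score"] = int(rng.integers(700, 1000))
    truth = SyntheticTruth(seed=seed, module=module,
                           params={"n_genes": n_genes, "attachment_m": attachment_m,
                                   "module_size": module_size,
                                   "ba_edge_count": ba_edges})
    return g, truth


def graph_edge_list(g: nx.Graph) -> list[tuple[str, str, int]]:
    """Scored edge records of a simulated graph, for the STRING writer."""
    return [(a, b, d["score"]) for a, b, d in g.edges(data=True)]


def simulate_immunotherapy_cohort(n_samples: int = 200, n_genes: int = 200,
                                  n_anchors: int = 5, effect: float = 1.0,
                                  noise_sd: float = 0.1, seed: int = 0,
                                  gene_names: list[str] | None = None,
                                  anchor_genes: list[str] | None = None,
                                  ) -> tuple[ExpressionMatrix, ResponseGrades, SyntheticTruth]:
    """Immunotherapy cohort with planted grade-monotone anchor genes.

    Response grades are uniform over {1..4} (redrawn if degenerate). Planted
    anchors express ``effect * grade + N(0, noise_sd)``; all other genes are
    N(0, 1) baseline noise. The matrix is shifted to be non-negative and
    tagged log2-scale.
    """
    if gene_names is None:
        gene_names = _gene_names(n_genes)
    if len(gene_names) != n_genes:
        raise ValidationError("gene_names length must equal n_genes")
    rng = np.random.default_rng(seed)
    if anchor_genes is None:
        anchor_genes = sorted(rng.choice(gene_names, size=n_anchors,
                                         replace=False).tolist())
    else:
        anchor_genes = list(anchor_genes)
        missing = set(anchor_genes) - set(gene_names)
        if missing:
            raise ValidationError(f"anchor genes outside the gene universe: {sorted(missing)}")
    if len(anchor_genes) >= n_genes:
        raise ValidationError("need fewer anchors than genes")

    for _ in range(100):
        grades = rng.integers(1, 5, size=n_samples)
        if len(np.unique(grades)) >= 2:
            break
    else:
        raise ValidationError("failed to draw non-degenerate response grades")

    values = rng.normal(0.0, 1.0, size=(n_genes, n_samples))
    idx = {g: i for i, g in enumerate(gene_names)}
    for a in anchor_genes:
        values[idx[a]] = effect * grades + rng.normal(0.0, noise_sd, size=n_samples)
    values -= values.min()

    samples = [f"P{i:04d}" for i in range(1, n_samples + 1)]
    expr = ExpressionMatrix(gene_names, samples, values, "log2")
    resp = ResponseGrades(samples, grades)
    truth = SyntheticTruth(seed=seed, anchors=anchor_genes,
                           noise_genes=[g for g in gene_names if g not in set(anchor_genes)],
                           params={"n_samples": n_samples, "n_genes": n_genes,
                                   "effect": effect, "noise_sd": noise_sd})
    return expr, resp, truth


def simulate_survival_cohort(n_samples: int, signature_genes: list[str],
                             beta: list[float], censor_rate: float = 0.05,
                             seed: int = 0, n_genes: int | None = None,
                             gene_names: list[str] | None = None,
                             baseline_hazard: float = 0.1,
                             sample_prefix: str = "S",
                             ) -> tuple[ExpressionMatrix, ClinicalTable, SyntheticTruth]:
    """Survival cohort with an exponential proportional-hazards law.

    Expression is standard normal per gene; the event time of a sample is
    Exponential with rate ``baseline_hazard * exp(beta . x_signature)``,
    censored by an independent Exponential(censor_rate) clock
    (``censor_rate=0`` disables censoring).
    """
    signature_genes = list(signature_genes)
    beta = [float(b) for b in beta]
    if len(beta) != len(signature_genes):
        raise ValidationError("beta must have one coefficient per signature gene")
    if gene_names is None:
        n_genes = n_genes or max(len(signature_genes), 1)
        gene_names = _gene_names(n_genes)
        # plant the signature on the first genes of a fresh universe
        gene_names = signature_genes + [g for g in gene_names
                                        if g not in set(signature_genes)]
        gene_names = gene_names[:max(n_genes, len(signature_genes))]
    missing = set(signature_genes) - set(gene_names)
    if missing:
        raise ValidationError(f"signature genes outside the gene universe: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, 1.0, size=(len(gene_names), n_samples))
    idx = {g: i for i, g in enumerate(gene_names)}
    lp = np.zeros(n_samples)
    for g, b in zip(signature_genes, beta):
        lp += b * values[idx[g]]
    rate = baseline_hazard * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if censor_rate > 0:
        t_censor = rng.exponential(1.0 / censor_rate, size=n_samples)
    else:
        t_censor = np.full(n_samples, np.inf)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    if event.mean() < 0.10:
        raise ValidationError(
            f"only {100 * event.mean():.1f}% events; lower censor_rate or "
            "raise baseline_hazard")

    samples = [f"{sample_prefix}{i:04d}" for i in range(1, n_samples + 1)]
    expr = ExpressionMatrix(gene_names, samples, values, "log2")
    clinical = ClinicalTable(pd.DataFrame(
        {"sample": samples, "time": time, "event": event}))
    truth = SyntheticTruth(seed=seed, signature_genes=signature_genes, beta=beta,
                           noise_genes=[g for g in gene_names
                                        if g not in set(signature_genes)],
                           params={"n_samples": n_samples,
                                   "censor_rate": censor_rate,
                                   "baseline_hazard": baseline_hazard})
    return expr, clinical, truth


def simulate_benchmark(seed: int = 0, n_genes: int = 300, module_size: int = 10,
                       n_anchors: int = 5, n_signature: int = 3,
                       effect: float = 1.0, noise_sd: float = 0.1,
                       n_immuno: int = 200, n_train: int = 400, n_test: int = 400,
                       beta_value: float = 1.0, censor_rate: float = 0.05) -> dict:
    """One coherent end-to-end scenario over a shared gene universe.

    The PPI graph carries a planted module; its first ``n_anchors`` members
    are the anchors of the immunotherapy cohort and the next ``n_signature``
    members carry the survival signal of the train/test cohorts.
    """
    ss = np.random.SeedSequence(seed)
    s_ppi, s_immuno, s_train, s_test = (int(c.generate_state(1)[0] % 2**31)
                                        for c in ss.spawn(4))
    graph, ppi_truth = simulate_ppi(n_genes=n_genes, module_size=module_size,
                                    seed=s_ppi)
    module = ppi_truth.module
    anchors = module[:n_anchors]
    signature_genes = module[n_anchors:n_anchors + n_signature]
    gene_names = sorted(graph.nodes)
    expr_immuno, grades, _ = simulate_immunotherapy_cohort(
        n_samples=n_immuno, n_genes=len(gene_names), effect=effect,
        noise_sd=noise_sd, seed=s_immuno, gene_names=gene_names,
        anchor_genes=anchors)
    beta = [beta_value] * n_signature
    expr_train, clin_train, _ = simulate_survival_cohort(
        n_train, signature_genes, beta, censor_rate=censor_rate, seed=s_train,
        gene_names=gene_names, sample_prefix="TR")
    expr_test, clin_test, _ = simulate_survival_cohort(
        n_test, signature_genes, beta, censor_rate=censor_rate, seed=s_test,
        gene_names=gene_names, sample_prefix="TE")
    truth = SyntheticTruth(seed=seed, anchors=anchors, module=module,
                           signature_genes=signature_genes, beta=beta,
                           params={"n_genes": n_genes, "effect": effect,
                                   "noise_sd": noise_sd, "censor_rate": censor_rate})
    return {"graph": graph, "expr_immuno": expr_immuno, "grades": grades,
            "expr_train": expr_train, "clin_train": clin_train,
            "expr_test": expr_test, "clin_test": clin_test, "truth": truth}
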