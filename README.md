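# gemscreen

Standardized comparative evaluation of genome-scale metabolic models.

Multiple constraint-based models of the same organism's metabolism —
the *Saccharomyces cerevisiae* collection being the canonical case —
disagree in two confounded ways: in the underlying network
reconstruction, and in the tunable parameters (simulated medium,
biomass objective function, reference lists of essential genes) chosen
when turning a reconstruction into a simulable model. `gemscreen` is a
toolkit for researchers who want to compare the *reconstructions*: it
imposes the same medium on every model, substitutes a common biomass
objective where the model's metabolites allow it, scores everything
against the same reference lists, and reports structure-level
statistics that are independent of parameters altogether.

What it computes:

- **Flux balance analysis** (FBA): maximize biomass flux subject to
  S·v = 0 and lb ≤ v ≤ ub, plus one-norm-minimised FBA for diagnosing
  flux loops, and flux variability analysis (FVA).
- **Single- and double-gene deletion screens** through boolean
  gene–protein–reaction (GPR) rules; a gene is essential when the
  mutant's maximal biomass flux is below 1e-6 flux units, and a pair of
  individually dispensable genes is synthetic lethal when the double
  mutant reaches ≤ 10% of wild-type flux.
- **Matthews Correlation Coefficient** scoring,

      MCC = (TP·TN − FP·FN) / √((TP+FP)(TP+FN)(TN+FP)(TN+FN)),

  with the positive class = *non-essential* (viable), and pooled
  cross-condition aggregation (MCC of summed counts, not mean of MCCs).
- **Network-structure statistics**: blocked reactions (FVA with all
  exchanges open) and dead-end metabolites (single-reaction, or
  produced-only / consumed-only under reversibility).
- **Model-scope comparison**: binary gene / ChEBI-metabolite incidence
  matrices, pairwise distances, hierarchical clustering (Newick
  export), classical multidimensional scaling.
- **Growth-correlation diagnostics**: biomass maxima under measured
  uptake constraints (singly or jointly), Pearson correlation against
  observed growth rates, and a one-norm loop-diagnosis /
  reaction-removal workflow.
- A **synthetic-data generator** that builds toy models with planted
  essential genes, synthetic-lethal isozyme pairs, dead ends and
  blocked reactions, so the whole pipeline is testable with provable
  ground truth and no downloads.

See `docs/methods.md` for the full description of the procedures,
parameters and their defaults.

## Worked example

```python
import gemscreen as gs

spec = gs.ToyModelSpec(n_linear_pathways=4, pathway_length=5,
                       n_isozyme_pairs=3, n_complexes=2,
                       n_parallel_routes=2, seed=42)
model, truth = gs.generate_toy_model(spec)
print(f"model: {len(model.genes)} genes, {len(model.reactions)} reactions")

singles = gs.single_deletion_screen(model)
print(f"wild-type biomass flux: {singles.wild_type_flux:.1f}")
print(f"predicted essential: {len(singles.essential_genes)} genes")

cm = gs.build_confusion_single(singles, set(truth.essential_genes))
print(f"vs planted truth: TP={cm.TP} TN={cm.TN} FP={cm.FP} FN={cm.FN}  "
      f"MCC={gs.mcc(cm):.3f}")

doubles = gs.double_deletion_screen(model)
doubles.singles = singles
cm2 = gs.classify_synthetic_lethality(singles, doubles,
                                      set(truth.synthetic_lethal_pairs))
print(f"double screen: {len(doubles.pairs)} pairs, "
      f"{len(doubles.synthetic_lethal_pairs)} predicted synthetic lethal, "
      f"MCC={gs.mcc(cm2):.3f}")
```

prints

```
model: 25 genes, 33 reactions
wild-type biomass flux: 10.0
predicted essential: 17 genes
vs planted truth: TP=8 TN=17 FP=0 FN=0  MCC=1.000
double screen: 300 pairs, 3 predicted synthetic lethal, MCC=1.000
```

The 17 predicted-essential genes are exactly the planted ones (the sole
catalysts of unbypassed pathway steps plus both members of each
two-gene complex), so all 8 dispensable genes land in TP, all 17
essential ones in TN, and the MCC is 1. The double screen evaluates all
300 unordered gene pairs and flags exactly the 3 planted isozyme pairs
as synthetic lethal. Scoring the same screen against a deliberately
corrupted reference (each label flipped with probability 0.1) drops the
MCC toward the closed-form expectation given by
`gs.expected_noisy_reference_mcc` — a calibration for how much
disagreement mere reference-list noise can explain.

## Command line

A thin CLI wraps the library:

```sh
gemscreen simulate --seed 4 --out toy/        # toy model + truth files
gemscreen screen-single toy/toy_seed4.tsv --out screen.tsv
gemscreen score screen.tsv toy/essential_truth.txt
gemscreen screen-double toy/toy_seed4.tsv --out pairs.tsv
gemscreen scope modelA.tsv modelB.xml --out scope/
gemscreen growth-scan model.xml observations.tsv --constrain glucose
gemscreen diagnose-loops model.xml --top 10
gemscreen run-all config.yaml                 # full comparison grid
```

`run-all` drives the models × media × biomass × reference-lists grid
from one YAML config, writes TSV tables (summary statistics, MCC
matrix, double-KO statistics), per-screen gene lists and a JSON
manifest, isolates per-cell failures, and exits nonzero if any cell
failed.

## File formats

- **SBML** Level 2 (COBRA-style kinetic-law bounds, notes-based gene
  associations) or Level 3 + FBC, via libSBML.
- A **flat TSV model dialect** for SBML-free toy work, with sections
  `[metabolites]` (id, name, compartment, `;`-joined ChEBI ids,
  boundary flag), `[reactions]` (id, name, `met:coeff;…`
  stoichiometry, bounds), `[gpr]` (reaction id, rule text), `[genes]`,
  and `[objective]`. Both formats round-trip exactly.
- **Media / biomass definitions** as editable YAML (templates under
  `src/gemscreen/data/media/`); component keys resolve per model by
  exchange id, metabolite id, then ChEBI id, with per-model supplement
  lists for models that need extra open exchanges.
- **Reference lists**: one ORF per line (essentiality), two
  tab-separated ORFs per line (synthetic-lethal pairs).

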