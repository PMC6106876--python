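# Methods

## Model

A pathway is a directed graph with signed edges (activation / inhibition)
whose nodes house zero or more genes. The unit of analysis is the
**effector circuit**: for a chosen effector node, the subgraph of all nodes
and edges lying on a directed path from any receptor to that effector.
Membership is *sign-agnostic* — inhibition edges transport (inhibitory)
signal, so they belong to circuits. On graphs with feedback loops,
membership generalizes from "on a simple path" to "reachable from a
receptor AND reaching the effector"; the two definitions coincide on DAGs
(verified against exhaustive path enumeration in the tests). Elementary
circuits (one receptor → one effector) are exposed as a second extractor.

Receptor and effector roles are taken from node annotations when any are
present; otherwise in-degree-0 nodes are receptors and out-degree-0 nodes
effectors. Self-loops are rejected by default (the recursion below is
underdetermined on them) and, when explicitly permitted, ignored for
membership.

Each node's value `v_n ∈ [0, 1]` proxies its protein's activity:
expression rows are min–max rescaled **per gene across samples** (a
constant row maps to 0.5), and multi-gene nodes take the **median** of
their member genes. Per-gene rather than global scaling keeps every gene's
between-sample variation on the same footing — with global scaling a few
highly expressed genes would compress everyone else's dynamic range. The
median is robust to one aberrant family member; mean and 90th-percentile
summaries are available. Nodes with no measured gene get a neutral default
of 0.5 — zero would permanently silence every circuit through the node, a
far stronger claim than "unmeasured".

Signal starts at 1 in every receptor and propagates by

    S_n = v_n · (1 − ∏_{s_a ∈ A}(1 − s_a)) · ∏_{s_i ∈ I}(1 − s_i)

(noisy-OR over activation inputs, multiplicative attenuation by inhibition
inputs, everything gated by the node's own value). Circuit activity is the
effector's S per sample. Two conventions close the recursion where the
formula alone is silent:

* **Basal activation.** The initial signal enters the receptor's
  activation set, so a receptor transmits S = v. A non-receptor node with
  *no* incoming activation edges (inhibition-only input) takes activation
  factor 1 instead of the empty product's 0; otherwise such nodes could
  never transmit at all.
* **Cycles.** On acyclic circuits one pass in (lexicographic) topological
  order is the exact fixed point. On cyclic circuits we iterate the map
  synchronously (Jacobi) from S⁰ = v until the largest per-node update
  falls below `tol = 1e-10`, capped at `max_iter = 10 000`. The map is
  continuous on [0,1]^N so a fixed point exists, but pure negative
  feedback at saturated values can oscillate; a damping factor
  (`new ← (1−d)·old + d·update`, default d = 1) resolves this, and
  non-convergence raises an error naming the circuit and sample — it is
  never silently accepted.

Products over incoming edges are accumulated in sorted predecessor-id
order, so results are bit-identical across runs and platforms.

## Statistics

**Differential activity.** Per circuit, a two-sided Wilcoxon rank-sum
(Mann–Whitney) test compares case vs reference activities: exact null
distribution when the pooled sample is ≤ 20 and tie-free, normal
approximation with tie and continuity corrections otherwise. P-values are
Benjamini–Hochberg-adjusted across all circuits of one comparison (one
comparison = one family). Status is UP when the case median exceeds the
reference median, DOWN when below; exact ties are reported UP with an
explicit tie flag.

**Function-level signal.** An effector→term table (GO-style id +
definition) attaches cell functions to circuits, keyed by effector label
with gene-symbol fallback. A term's activity per sample is the arithmetic
mean of its member circuits' activities — order-independent, stays in
[0, 1], and a single-circuit term reproduces that circuit exactly; median
and max are available since no canonical aggregation exists for this
quantity.

**Survival screen.** For each circuit and each tail, the
k = round(0.10·n) samples (floor 2) with the highest (or lowest) activity
are compared to the rest with the standard unweighted (rho = 0) log-rank
test; ties spanning the cutoff are broken by ascending sample id so the
split is deterministic and exactly size k. Kaplan–Meier curves per stratum
use the product-limit estimator (via lifelines). FDR adjustment defaults to
the joint family of all circuit × tail tests — the conservative choice; a
per-tail family is available. Constant-activity circuits and strata without
events are reported as skipped rows, not silently dropped, and samples
lacking survival data are dropped with a count in the output.

## Synthetic data

The generator emulates all four inputs with known ground truth, under a
single integer seed:

* **Pathways** — layered random DAGs (defaults: 12 nodes, 2 receptors,
  2 effectors, 4 layers, edge probability 0.35, inhibition fraction 0.25,
  1–3 genes per node). Every non-receptor is guaranteed an incoming edge
  from the previous layer, so decomposition always succeeds. Optional
  backward edges between middle layers create feedback loops.
* **Expression** — i.i.d. Normal(5, 1) truncated at 0 per gene and sample,
  a rough stand-in for a log2(1 + FPKM) scale. Group effects are planted
  by shifting the member genes of selected circuits by ±δ · (per-gene
  range) in case samples (default δ = 0.3) — on *genes*, not activities,
  so recovery genuinely exercises normalization, node summarization and
  propagation. The default cohort is 60 case + 60 reference samples.
* **Survival** — exponential event times with baseline hazard 0.1,
  multiplied by a hazard ratio (default 3) for the top activity decile of
  a planted circuit, mirroring the screen's own stratification design.
  Censoring times are Uniform(0, u) with u solved numerically so the
  expected censored fraction hits the configured rate (default 0.30).
* A manifest records the full spec; regeneration from it is byte-identical.

What the generator does **not** emulate: RNA-seq count noise (negative
binomial reads), batch effects, gene–gene correlation beyond the planted
circuit structure, non-proportional hazards, informative censoring.
Passing tests therefore demonstrate correctness of the algorithms and
calibration of the statistics under clean conditions, not robustness to
the full messiness of real cohorts.

## Verification studies

`pathcircuit.studies` holds deliberately naive reference implementations
used only for checking: a memoized recursive evaluator (vs the topological
pass; agreement ≤ 1e-12 over 200 random DAG circuits), a long-run
brute-force fixed-point iteration in plain floats (vs Jacobi on 25 cyclic
fixtures; agreement ≤ 1e-8 — the oracle stops early only once a sweep
moves nothing by more than 1e-15, below the comparison's resolution), a
hand-rolled BH step-up, exact rank-sum enumeration, hand product-limit
tables and a from-scratch log-rank O−E/V accumulation. The simulation
studies measure: null calibration of the differential stage (100
replicates × 200 independent single-circuit pathways, 60+60 samples;
pooled raw p-values KS-tested for uniformity, false-call fraction at FDR
0.05), its power (δ = 0.3 planted on 5 of 200 circuits, 50 replicates;
planting is restricted to activation-only circuits so the direction of the
activity response is structurally unambiguous), and the survival screen's
null calibration and recovery (hazard ratio 3 on the top decile of 1 of
100 circuits, n = 500, 30% censoring, 100 replicates). These sizes are the
package's documented study conditions and are what `scripts/acceptance.py`
reruns.

## Numerical and design notes

* Calibration studies use many small single-effector pathways rather than
  few large ones so that the tested p-values are independent across
  circuits — the regime in which KS uniformity is a meaningful check.
* Stage outputs are TSV with `#` metadata comments and a fixed float
  format (`%.12g`), making reruns byte-comparable and diffs readable.
* `differential_activity` sorts by adjusted p then circuit id; all other
  tables have similarly deterministic orderings (stable sorts
  throughout).
* The pipeline refuses unconverged propagation states; the CLI maps
  configuration, data and convergence failures to exit codes 2, 3, 4.

## Known limitations

* Real KEGG KGML parsing is out of scope; pathways enter via the JSON
  schema or SIF-like edge lists (a KGML converter is a natural extension).
* Function-level aggregation has no canonical definition; the mean is a
  declared choice, not a derived one.
* The 10% stratification uses strict ranks with id tie-breaking, which can
  split tied activity values arbitrarily (deterministically, but
  arbitrarily) across the cutoff.
* Cox modeling, covariate adjustment and hazard-ratio estimation are out
  of scope — the screen is a detector, not an effect estimator.
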