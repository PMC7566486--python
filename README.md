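# colocnv

Discovery of **genomically co-localized co-expression signatures** in
multi-cohort tumor expression data, and designation of the signatures that
are **driven by recurrent copy-number alterations** (amplicons and deleted
regions).

## The problem

Recurrent somatic amplifications and deletions reshape tumor transcriptomes
through gene dosage: when a chromosomal segment is amplified in a subset of
tumors, the genes it carries rise and fall together across samples. A block
of physically adjacent, strongly co-expressed genes whose shared expression
tracks the local copy number — across many cancer types at once — is
therefore strong evidence for a pan-cancer driver alteration carrying
cooperating oncogenes or tumor suppressors. The analysis has to separate
such blocks from co-expression that has nothing to do with copy number
(immune infiltration, proliferation programs), which is abundant and strong
in bulk tumor data.

## The method

**Association measure.** For sample-indexed vectors *a*, *b* the package
uses a B-spline mutual-information estimate (six soft bins per dimension,
spline order 3), normalized and signed:

    assoc(a, b) = sign(ρ(a, b)) · I(a; b) / max(I(a; a), I(b; b)) ∈ [−1, 1]

Per-cohort associations are aggregated into a *pan-cancer* association by a
lower weighted median, each cohort weighted by its share of tumor samples.

**Windowed attractor signatures.** Genes are ordered by genomic midpoint.
Every gene seeds an iteration restricted to its nearest *S* = 150 genes
(*S*/2 per side, truncated at chromosome ends): each cohort's metagene is
the expression average of the window genes with mixing weights
max(w, 0)^α (α = 2), and each gene's weight w is its pan-cancer association
with the metagene; iterate to a fixed point (ℓ∞ change < 10⁻⁷). The
signature **strength** is the fifth-highest weight — strength ≥ 0.5 means
at least five strongly co-expressed genes. Overlapping signature ranges
(member genes with weight > 0.5) are merged, each merged range is re-seeded
from all its genes and represented by the strongest attractor, and
signatures with mostly unexpressed top genes or on chromosomes X/Y are
dropped.

**Driver designation.** A signature's expression level and CNA level per
sample are the means over its top five genes. A driver must satisfy both:

1. *Association*: the pan-cancer expression/CNA association beats a
   permutation null (10,000 within-cohort sample permutations; per-cohort
   nulls sorted and combined rank-by-rank with the weighted median;
   Bonferroni over tested signatures, P < 0.05).
2. *Frequency*: amplification (deletion) frequency — the fraction of tumors
   with CNA level above t_amp (below t_del) — strictly exceeds 3% in
   strictly more than 6 cancer types. t_amp and t_del are the weighted
   medians of the per-cohort means of the top/bottom decile of
   per-sample-centered normal-tissue CNA.

Adjacent same-direction drivers are additionally checked for
co-amplification (CNA levels within 0.1 in altered samples).

A synthetic multi-cohort generator with planted amplicons, deletions,
dosage coupling and copy-number-neutral confounder blocks provides ground
truth for every stage; no external data is needed.

## Worked example

The numbered scripts under `analysis/` run the full study on synthetic
cohorts (eight cohorts, 950 tumors, 600 genes, three planted amplicons, one
planted deletion at 10% event frequency, one copy-number-neutral
confounder):

```bash
python analysis/01_simulate_cohorts.py --seed 1
python analysis/02_discover_signatures.py
python analysis/03_call_drivers.py --seed 1
python analysis/04_score_recovery.py
```

which prints (seed 1):

```
5 signatures survive strength and expression filters:
   name  chromosome  strength  n_members range_first range_last
g1_0038           1  0.779944         14     g1_0030    g1_0043
g1_0156           1  0.775901         13     g1_0150    g1_0162
g2_0071           2  0.776579         13     g2_0060    g2_0072
g3_0032           3  0.723744         12     g3_0030    g3_0041
g3_0147           3  0.775349         15     g3_0140    g3_0154

t_amp=0.202, t_del=-0.211; 5 signatures -> 4 association-passing
  -> 4 frequency-passing -> 4 drivers (3 amplified, 1 deleted)
precision=1.00 recall=1.00 over 4 planted events
```

All four planted events are recovered exactly (member-gene Jaccard 1.0).
The fifth signature (`g3_0032`) is the planted copy-number-neutral
confounder: it is strongly co-expressed (strength 0.72) but fails *both*
driver conditions (permutation P ≈ 1 and no recurrent alteration), which is
precisely the separation the dual rule is designed to enforce. The two
adjacent chromosome-1 amplicons are reported with a co-amplification
frequency of ~2% and near-zero expression association — they are
independent events that happen to be neighbors.

The same pipeline is scriptable as `colocnv simulate|discover|call|score|run`
(see `colocnv --help`) with a YAML configuration.

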