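# bhtreesim

Stochastic simulation of phylogenetic trees under generalized branching
processes. Each lineage carries competing clocks for speciation and
extinction whose waiting times come from **arbitrary user-chosen
distributions** (exponential, Weibull, gamma, uniform, lognormal,
zero-truncated normal, constants, or registered custom generators), so the
classic Yule and constant-rate birth–death models, age-dependent models and
proportional-to-distinguishable-arrangements behaviour are all special
cases of one engine.

Features:

* **Symmetric or asymmetric (budding) speciation** — either both daughters
  are new species of age 0, or the mother persists with her age and
  scheduled extinction time and speciates repeatedly.
* **Heritable lineage-specific shifts** — with a configurable probability a
  new species scales its speciation and/or extinction waiting times by a
  factor drawn from a strength distribution; factors are inherited until
  shifted again, and every node is annotated with its factors and 0/1
  shift flags.
* **Stopping rules** — fixed stem age, first passage to *n* coexisting
  species, or the general sampling approach (simulate to *m ≫ n* species
  and cut uniformly over all periods with exactly *n* coexisting lineages,
  avoiding the young-tree bias of first-passage stopping).
* **Pruning & incomplete sampling** — keep the complete tree or prune
  extinct lineages to the reconstructed ultrametric tree; optionally sample
  tips uniformly or proportionally to pendant branch lengths.
* **Reproducibility** — replicate *k* of a batch runs on a substream
  derived from `(master_seed, k)`; identical seeds give bitwise-identical
  Newick output.

## Python API

```python
import bhtreesim as b

# 100 pure-birth trees with exactly 20 extant species
cfg = b.SimConfig(waitsp="rexp(0.5)")
results = b.run_batch(cfg, 100, b.TaxaStop(n=20), master_seed=1)

# birth-death trees of age 4 with Weibull (age-dependent) speciation
cfg = b.SimConfig(waitsp="rweibull(0.4,3)", waitext="rexp(0.5)",
                  mode="asymmetric")
res = b.simulate_age(cfg, age=4, stream=b.RandomStream(7))
print(b.write_newick(res.tree))

# lineage-specific shifts: 9% of new species scale their speciation
# waiting times by a factor drawn uniformly from [0.5, 1.5]
cfg = b.SimConfig(waitsp="rexp(0.8)",
                  shiftsp=b.ShiftConfig(prob=0.09, strength="runif(0.5,1.5)"))
res = b.simulate_taxa(cfg, n=15, stream=b.RandomStream(3))
print(b.shift_report(res.tree).table.head())
```

Waiting-time specs use the R-style generator-call dialect: the implicit
"number of observations" argument is never written, remaining parameters
are positional with the generator's defaults (`"rweibull(0.4)"` means
shape 0.4, scale 1; `"rgamma(1.5,1,2)"` means shape 1.5, rate 1, scale 2
with the scale overriding the rate). `const(x)` is a fixed waiting time and
`register_generator(name, fn)` plugs in any callable returning one waiting
time per call. Omitting `waitext` means no extinction.

`simulate_age` returns a `SimResult` whose status is `completed`,
`extinct` (no lineage survived; no tree) or `single_survivor` (one lineage
survived and `complete=False`). Event counts and total alive lineage-time
are recorded for every replicate so `estimate_event_rates` can pool
unbiased constant-rate estimators across a batch.

## Command line

```sh
# 100 birth-death trees of age 4
bhtreesim age --age 4 --numbsim 100 --waitsp "rexp(0.9)" --waitext "rexp(0.1)" \
    --seed 1 --out trees.nwk --annotations shifts.tsv --summary summary.tsv

# 100 Yule trees on 20 taxa via the general sampling approach
bhtreesim taxa --n 20 --gsa --m 200 --numbsim 100 --waitsp "rexp(0.5)" --seed 1
```

Trees are written as Newick, one per line, with the stem emitted as the
trailing root edge length; extant tips are labelled `t1, t2, ...` and
extinct tips `x1, x2, ...`. Shift annotations go to a sidecar TSV (or
inline as NHX comments with `--nhx`). A flat `key = value` config file
(`--config`) can replace the flags; keys mirror the option names
(`numbsim`, `age`/`n`, `m`, `gsa`, `waitsp`, `waitext`, `symmetric`,
`complete`, `shiftsp.prob`, `shiftsp.strength`, `shiftext.prob`,
`shiftext.strength`, `frac`, `sampling_method`, `seed`). The exit code is
nonzero when every replicate goes extinct.

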