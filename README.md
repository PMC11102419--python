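# divindex

Phylogenetic diversity indices on rooted edge-weighted trees, with exact
arithmetic throughout: scoring, index classification, extinction analysis and
constructive edge-length assignments that completely reverse the ranking of
surviving species.

## What it does

* **Tree core** — rooted phylogenetic trees with exact rational branch
  lengths (decimal or `p/q` Newick notation), structural queries (clusters,
  m-cherries, isolated leaves, canonical shape keys, `~`-equivalence classes,
  ultrametricity) and extinction-induced subtree computation with
  unifurcation suppression and length merging.
* **Index framework** — diversity indices expressed as local
  ratio-of-allocation rules (child shapes → proportions), converted to
  coefficient tables in consistent form.  Built-ins: Fair Proportion (`fp`),
  Equal-Splits (`es`) and the example family `alpha`, `beta`, `gamma_min`,
  `delta_cherry`, `epsilon_singleparent`, `zeta_squares`, `eta_hybrid`, plus
  table-defined rules.  Interior/boundary classification and a rigidity
  probe (witness search over singular classes).
* **Extinction analysis** — necessary-deletion lower bounds, symbolic
  fixed-leaf detection, per-survivor score-change functionals, and exact
  ranking comparison (strict and relaxed reversal verdicts, Kendall-style
  concordance counts).
* **Reversal constructions** — the big-M/infinitesimal assignment for rigid
  interior indices (symbolic `a + b*eps` arithmetic; published worked values
  are reproduced exactly in the `eps -> 0` limit) and the recursive
  interleaving construction for non-rigid interior indices.  Certificates
  are always re-verified from scratch, and provably impossible instances
  (two survivors with identical score-change functionals) are diagnosed
  rather than looped on.
* **Ultrametric analysis** — necessary conditions for Fair Proportion
  reversals under the clock constraint and a generator for the reversible
  ultrametric family (`generate_U(n)` for even `n >= 6`).
* **Fixtures** — the 11-leaf worked-example tree, the 12-leaf ultrametric
  tree and seeded synthetic generators (binary / multifurcating /
  caterpillar / ultrametric), so everything is testable offline.

## CLI

```sh
divindex score      --fixture fig3 --index fp --precision 2
divindex classify   --fixture fig3 --index beta
divindex extinct    --fixture fig3 --index fp --remove x2,x5 --report json
divindex reverse    --fixture fig3 --index es --method thm9 --big-m 32 \
                    --certificate cert.json --out lengths.nwk
divindex ultracheck --fixture u12 --index fp --remove even-index
divindex ufamily    --n 12 --out u12.nwk
divindex fixtures   --list
```

`--tree file.nwk` accepts any rooted Newick file in place of `--fixture`.
Exit codes: `0` success, `2` precondition violation, `3` verification
failure.

## Library example

```python
from fractions import Fraction
from divindex import builtin_rule, scores, theorem9_construct
from divindex.fixtures import fig3_tree

tree = fig3_tree()
print(scores(tree, builtin_rule("fp"))["x3"])   # 113/60

workings, cert = theorem9_construct(tree, builtin_rule("es"), M=Fraction(32))
print(cert.valid, [x for x in workings.survivor_order])
```

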