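# trihp

Hydrophobic–polar (HP) protein structure prediction on the **2D
triangular lattice**, using a genetic algorithm with an elite-based
reproduction strategy (ERS-GA) and a hybrid that embeds hill-climbing
local search in the reproduction loop (HHGA).

## The problem

In the HP lattice model each residue of a protein is classified as
hydrophobic (**H**) or polar (**P**), and a conformation is a
self-avoiding walk (SAW) of the chain on a lattice. The free energy of
a conformation counts topological H–H contacts:

```
E(c) = -|{(i, j) : j > i + 1,  s_i = s_j = H,  |x_i - x_j| = 1}|
```

i.e. −1 for every pair of H residues that are not adjacent in the
sequence but occupy neighboring lattice sites. Structure prediction is
the combinatorial optimization problem `min E(c)` over all SAWs, which
is NP-complete. The triangular lattice gives every site six neighbors,
which removes the square lattice's parity restriction (there, residues
at even sequence separation can never touch) and lets each residue form
up to four H–H contacts.

A conformation of an *n*-residue chain is encoded as a fold string of
length *n* − 1 over the six absolute step directions
`{L, R, LU, LD, RU, RD}`. The ERS-GA evolves a population of 200 fold
strings for 200 generations: each generation the fitter half survives
unchanged and the other half is replaced by offspring bred by two-point
crossover (rate 0.8) and uniform mutation (rate 0.4). The HHGA
additionally refines every offspring with two hill climbers — single
direction changes accepted on strict improvement, and best-of-five
rigid rotations (60°…300°) of the tail segment after a random pivot.
Self-colliding chromosomes are admitted into the population but pay a
dominating penalty per colliding pair, so every returned best is a
valid SAW. An exhaustive-enumeration oracle gives exact optima for
chains of up to ~12 residues.

## Worked example

```python
>>> import trihp
>>> seq = trihp.parse_hp_notation("(HP)^2PH(HP)^2(PH)^2HP(PH)^2")
>>> seq, len(seq)
('HPHPPHHPHPPHPHHPPHPH', 20)
>>> res = trihp.run_hhga(seq, trihp.GAConfig(seed=4))
>>> res.best_energy
-15
>>> trihp.folds_to_symbols(res.best_conf)
'R-LD-R-LD-L-LU-LD-LU-L-RU-R-LU-R-LU-RU-R-LD-R-LD'
>>> trihp.energy(seq, res.best_conf)
-15
```

The 20-residue benchmark chain folds to energy −15, i.e. 15 H–H
contacts — the known best for this sequence on the triangular lattice.
For a chain this short the exhaustive oracle can verify small cases
exactly:

```python
>>> trihp.enumerate_min_energy("HHHH")
OracleResult(min_energy=-2, optimal_count=3, one_optimum=array([0, 1, 3]))
```

From the shell:

```
trihp run --seq-id 2 --algorithm hhga --runs 30 --seed 1 --out results.tsv
trihp oracle --sequence "(HP)^3"
trihp bench --all --algorithm both --out report/
```

`trihp bench` prints, per benchmark, the mean and best energy over the
configured runs and flags whether the best matched, beat, or fell short
of the published value for that algorithm.

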