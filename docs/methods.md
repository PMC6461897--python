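# Methods

## The scoring model

A docking campaign produces, per ligand, an ensemble of poses with engine
binding energies E_i (kcal/mol, more negative = more favorable). The score
implemented here corrects the raw minimum for how densely the engine
repopulated the same pose basin:

    ΔG = E_min − kT · ln N

where E_min is the lowest energy among the N poses of one COM cluster.
The entropy term −kT ln N is a configurational-stability proxy, not a
statistical-mechanical free energy: it assumes each pose in the cluster is
an independent rediscovery of the same binding mode, so a basin found 521
times is rewarded by −kT ln 521 ≈ −3.71 kcal/mol over a singleton. ΔG ≤
E_min always, with equality iff N = 1, and ΔG is strictly decreasing in N
at fixed E_min. Ligands are ranked by their best (minimum) cluster ΔG;
ties are broken by larger N, then ligand id, for total determinism.

Temperature is not part of the input data, so the package defaults to
T = 298.15 K with k_B = 0.0019872041 kcal/(mol·K), giving kT ≈ 0.59248
kcal/mol. Both are overridable, and every report embeds the values used:
between 298.15 K and 300 K the 91-member example above moves by less than
0.02 kcal/mol, so the default is not load-bearing for rankings at typical
cluster sizes.

A consequence worth noting: the worked three-ligand example has E_min =
−7.9 kcal/mol for a 91-member cluster and ΔG = −10.95 kcal/mol for a
521-member cluster. Inverting the formula gives the 521-cluster's implied
raw minimum as −10.95 + kT ln 521 ≈ −7.24 kcal/mol — weaker than −7.9.
The entropy term alone flips the ranking, which is exactly the behaviour
the score is designed to expose.

## Clustering

Poses are reduced to their center of mass — the mass-weighted mean of atom
coordinates, using standard atomic weights (a geometric-centroid mode
exists because docking files often omit hydrogens and carry nonstandard
atom types; an unknown element falls back to carbon's mass with a logged
warning rather than aborting a run). Clustering is the greedy **leader**
rule at a fixed radius (default 4 Å):

* visit poses in ascending energy, ties broken by ascending pose index;
* a pose joins the earliest-created cluster whose **representative** COM is
  within the radius (closed comparison, Euclidean distance), else founds a
  new cluster with itself as representative.

Anchoring the distance test on the representative rather than a running
centroid keeps the partition deterministic and makes "lowest-energy member
is the representative" true by construction, since seeding is
energy-ordered. The partition is disjoint and exhaustive; `partition_check`
revalidates all of this on any output. No RMSD or hierarchical clustering
is offered — the clustering coordinate is the COM by design.

Properties the test suite enforces: exact agreement with an independently
written naive leader implementation on random small ensembles; one cluster
when the radius exceeds the COM diameter and all singletons when it is
below the minimum pairwise distance; invariance of every cluster statistic
under a common rigid motion of all poses.

## Site boxes

A binding site is given as a residue list (one-letter code + number,
optional chain, e.g. `A:S181`). Each residue contributes an axis-aligned
cube centered on its Cα atom. "15 Å box" is interpreted as **edge** 15 Å
(half-width 7.5 Å), the usual docking box-size convention; the edge is
configurable for readers who intend half-width. Residue lookup verifies
the structure's residue identity against the one-letter code and errors on
mismatch, missing residue, missing Cα, or an ambiguous chain — guessing a
chain silently is worse than failing. Site membership of a pose is tested
on its COM against the closed union of cubes; an any-atom-overlap mode is
deliberately out of scope since the clustering geometry is COM-based too.

## Synthetic ensembles

`simulate_ensemble` plants a known cluster structure: cluster k receives
`cluster_sizes[k]` poses whose COMs are the cluster center plus a
displacement drawn uniformly in a ball of radius `scatter_max`
(rejection-sampled, hard truncation — not a Gaussian), and energies
`energy_base[k]` plus Gaussian jitter. Atom coordinates are a rigid
all-carbon template shifted so the realized COM equals the target COM.
In **guarantee mode** (the default: centers pairwise ≥ 2·radius + 0.5 Å
apart, scatter ≤ radius/2), recovery of the planted partition by leader
clustering is a theorem, not a probability: within-cluster COM distances
are ≤ 2·scatter ≤ radius while between-cluster distances are
> 2·radius − 2·scatter ≥ radius. Every test that asserts 100/100-seed
recovery relies on this construction, which is why truncated scatter was
chosen over unbounded noise (an unbounded mode remains available by
switching the guarantee off).

What the generator does *not* emulate: real ligand chemistry (torsions,
element diversity beyond the COM arithmetic), the docking engine's energy
model, or the anisotropic, multi-basin scatter of real pose pools. Passing
the recovery and ranking tests therefore demonstrates correctness of the
clustering/scoring machinery, not that a 4 Å COM radius is the right
granularity for any particular receptor.

All randomness flows through one `numpy.random.Generator` per call,
derived from the spec's seed; identical seeds give bit-identical pose
tables.

## Numerical and I/O choices

* Energies and coordinates are preserved verbatim from input files; the
  pose table writes floats at full precision (`repr`) so
  read(write(x)) == x bit-exactly, while reports render at 4 decimals for
  diffability.
* The PDBQT reader takes each MODEL block's energy from the first numeric
  token after `REMARK VINA RESULT`, tolerant of formatting drift across
  engine versions; a MODEL without an energy REMARK is a parse error that
  names the block. A file with no MODEL blocks is accepted as a single
  pose only if it carries an energy REMARK.
* Receptor PDBs are parsed with gemmi; for alternate locations only the
  first conformer is kept (dropped copies logged). HETATM records are
  retained but flagged and excluded from residue lookup.
* Hydrogens are neither added nor removed; Vina-style PDBQT typically
  carries polar hydrogens only, and reproducibility is preferred over
  chemical completeness.
* An ensemble whose poses disagree in atom count or atom-name sequence is
  rejected unless `allow_heterogeneous` is set, since a COM comparison
  across different molecules is rarely meaningful.

## Problem sizes

The test suite and the acceptance script run entirely on synthetic data:
200 random ensembles of ≤ 12 poses for the oracle cross-check, 100 seeds
of the 27/91/521-pose campaign (639 poses each) for recovery, and direct
formula evaluations elsewhere. These sizes fully exercise every code path
— leader clustering is O(poses × clusters) and needs no larger inputs to
be validated.

## Known limitations

* The score is the literal heuristic ΔG = E_min − kT ln N on signed
  engine energies; it is not MM-PBSA/FEP and carries no solvation or
  conformational-entropy physics. Published *positive* per-cluster
  "average energy" values seen in some reports of this workflow cannot be
  reconciled with signed Vina-style affinities; this tool reports signed
  means and leaves that discrepancy documented rather than emulated.
* Whether pose pools should be merged across residue-centered docking runs
  before clustering is a study-design question; the tool clusters whatever
  ensembles it is given, per input file.
* Leader clustering is order-dependent by definition; the energy-ascending
  visit order is part of the method's contract, not an implementation
  detail.
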