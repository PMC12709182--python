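# rnatopo

A toolkit for analysing and engineering the **topology of RNA contact
maps** used as distance restraints in 3D structure prediction.

Coevolution- and ML-based contact predictors are usually judged by their
positive predictive value (PPV) alone, yet contact maps with identical
PPV can fold very differently: convolutional predictors tend to place
contacts in dense clusters, and clustered restraints carry less
independent geometric information than dispersed ones. `rnatopo`
quantifies that dispersion, builds contact selections of controlled
topology, and evaluates their effect. It is aimed at developers of RNA
contact predictors and at anyone preparing restraint sets for folding
engines such as SimRNA.

## The Gaussian score

For a set of contacts $\mathcal{C}$ with upper-triangle positions
$\mathbf{r}_i = (i, j)$ on the $L \times L$ map, each contact receives a
Gaussian kernel density

$$\nu_i = \sum_{j \in \mathcal{C}} \exp\!\left[-\frac{(\mathbf{r}_i - \mathbf{r}_j)^2}{\sigma^2}\right],$$

is down-weighted by inversion, $\omega_i = \nu_i^{-1}$, and the score is
the total weight

$$\Omega = \sum_{i \in \mathcal{C}} \omega_i, \qquad 1 \le \Omega \le |\mathcal{C}|.$$

Isolated contacts contribute ≈ 1 each, contacts packed into clusters
share weight, so small $\Omega$ means a clustered topology and
$\Omega \to |\mathcal{C}|$ a maximally dispersed one. $\Omega/L$
normalizes across molecule sizes, and a continuous relaxation
(`soft_gauss_score`) accepts probability-valued maps so the score can
serve as a loss-function term in predictor training (default
$\sigma^2 = 4$).

Around this core the package provides:

* **Contact extraction** from PDB/mmCIF structures under the two standard
  definitions: N1/N9 nitrogen atoms ≤ 9.5 Å, or closest heavy atoms
  < 10 Å, with a configurable minimum sequence separation (default 4).
* **Selection schemes** for a restraint budget of $n$ contacts (default
  $L/2$): `clustered` (largest connected cluster first, emulating CNN
  output), `random` (uniform), and `gauss` (greedy + single-swap
  maximization of $\Omega$).
* **False-contact injection** at a target error rate $\lambda$, with the
  identity $\mathrm{PPV} = 1 - \lambda$ by construction.
* **Evaluation**: PPV, error rate, the Hopkins clustering-tendency
  statistic of a selection, the beneficial fraction
  $\xi = \tfrac{1}{|\mathfrak{D}|}\sum_{\mathfrak d} \Theta[\mathrm{RMSD}_{\mathrm{free}} - \mathrm{RMSD}_{\mathrm{restrained}}]$
  (strict improvement; ties do not count), and a Kabsch-superposition
  RMSD utility.
* **Restraint export**: selected contacts as flat-bottom distance
  restraints between N1/N9 reference atoms, in a SimRNA-style column
  format.
* **Synthetic generators** for toy hairpin structures, planted-topology
  contact maps, and RMSD tables, so everything runs without downloads.

## Worked example

```python
import rnatopo as rt

# a planted-topology map: two helix stems plus one blob-like patch
cmap = rt.generate_synthetic_contact_map(
    L=80, stems=[(5, 40, 8), (20, 70, 8)],
    patches=[((15, 55), 4, 0.8)], seed=0,
)
print("native contacts:", len(cmap))                 # 54
print("cluster sizes:", rt.find_clusters(cmap).sizes())  # [38, 8, 8]

for name, sel in [
    ("clustered", rt.select_clustered(cmap, n=25, seed=0)),
    ("random", rt.select_random(cmap, n=25, seed=0)),
    ("gauss", rt.select_gauss_optimized(cmap, n=25)),
]:
    print(name, rt.gauss_score(sel.as_contact_map()),
          rt.hopkins_statistic(sel, seed=0))
```

prints

```
clustered  Omega =   5.73   Hopkins = 0.939
random     Omega =  10.17   Hopkins = 0.881
gauss      Omega =  14.27   Hopkins = 0.836
```

The clustered selection concentrates 25 contacts in the big patch (low
$\Omega$, Hopkins near 1 = strongly clustered); the Gaussian-optimized
selection disperses them (highest $\Omega$, lowest Hopkins). Diluting a
selection with 25 % false contacts gives `ppv(...) == 0.75` exactly, and
a synthetic RMSD table with improvement probability 0.7 recovers a
beneficial fraction near 0.7.

The same workflows are available on the command line:

```sh
rnatopo make-fixtures fixtures --seed 0
rnatopo extract-contacts fixtures/toy_hairpins.pdb -o native.txt
rnatopo select native.txt --scheme gauss --n 10 --seed 7 -o sel.txt
rnatopo inject sel.txt --native native.txt --lam 0.25 --seed 1 -o diluted.txt
rnatopo ppv diluted.txt native.txt
rnatopo restraints sel.txt --sequence GGGGGAAAACCCCC
```

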