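# scwnet — interaction networks of supercritical water

`scwnet` characterizes the microstructure of (supercritical) water as a
complex network.  Above the critical point (T_c = 647.096 K, P_c =
220.64 bar) the hydrogen-bond system is largely broken down and the fluid
is a fluctuating mixture of transient molecular clusters; `scwnet` detects
those clusters in snapshots of rigid four-site water (the TIP4P/2005
family: H_a, O, M, H_b sites), quantifies their topology, and connects
them to the electronic character of the underlying contacts.

It is aimed at molecular-simulation practitioners who have trajectory
frames (fixed-width GRO-style files) and, optionally, QTAIM
bond-critical-point tables from downstream quantum-chemistry runs, and who
want cluster statistics, network metrics and interaction classes rather
than radial distribution functions alone.

## The model

Two molecules *i*, *j* are **energetically connected** when

```
V_Coulomb(i,j) + V_LJ(i,j) + E_kin(i,j) + λ·4·E_kin_H  <  0
```

* `V_Coulomb` — Coulomb sum over the charged sites (H_a, H_b, M) of both
  molecules;
* `V_LJ` — the oxygen–oxygen Lennard-Jones term, the only LJ interaction
  in the four-site model;
* `E_kin(i,j) = ½ μ |Δv_com|²` — kinetic energy of the pair's relative
  motion (μ = m_w/2);
* `E_kin_H` — kinetic energy of a hydrogen-mass particle at the
  Maxwell–Boltzmann most probable speed, which equals R·T per mole;
* `λ` — a phenomenological weight on the thermal penalty of the four
  hydrogens in the pair, calibrated against a reference cluster-size
  distribution (default 0.655).

A candidate pair is discarded when any third body lies inside a finite
**interference cylinder** of radius r_c = σ_OO = 0.3159 nm along the
COM–COM segment (only interference-free pairwise interactions count), and
molecules outside a concentric cube of 85% of the box edge are dropped in
place of minimum-image bookkeeping.  On the resulting graph the package
computes the network density ρ = 2E/(N(N−1)), average degree ⟨k⟩ = 2E/N,
PageRank, and connected components, and fits the component-size
distribution to the power law

```
n_c(s) = A · s^b
```

where A tracks the monomer count and b the decay of cluster frequency
with size s.  QTAIM bond-critical-point tables (ρ, ∇²ρ, G, K,
V = −G − K, H = G + V) are classified into noncovalent
(∇²ρ > 0, H > 0), partially covalent (∇²ρ > 0, H < 0) and covalent
(∇²ρ < 0, H < 0) contacts, with Kruskal–Wallis/ANOVA comparisons across
thermodynamic conditions.

## Worked example

`examples/build_network_from_planted_clusters.py` plants 10 monomers,
5 dimers and 2 trimer chains, runs the full pipeline at λ = 0.655 and
T = 673 K, and prints:

```
molecules: 26, edges: 9
component sizes n_c(s): {1: 10, 2: 5, 3: 2}
planted truth recovered: True
network density (all nodes): 0.0277
average degree <k>:          0.6923
PageRank mean (interacting): 0.0571
```

The 9 edges are exactly the planted hydrogen bonds (5 dimer bonds + 2×2
chain bonds); the component-size counts recover the planted distribution,
and the metrics summarize how sparse the resulting network is (ρ ≈ 0.03 of
all possible pairs are connected; an average molecule has ⟨k⟩ ≈ 0.69
partners).  The other scripts in `examples/` demonstrate λ calibration
(recovering a generating λ₀ = 0.5 with zero MAE), PCA-based selection of
representative frames and components, BCP classification (89.5%
noncovalent / 10.5% partially covalent on a synthetic table), and the
reduced-state/density validation screen (13 of 15 stored conditions pass
the 5% density-error threshold).

A `scwnet` CLI wraps the same functionality
(`scwnet simulate | build-network | metrics | components | fit-powerlaw |
calibrate-lambda | select-frames | classify-bcp | compare-groups`); every
subcommand writes JSON with a `parameters` block recording the effective
settings.

## Layout

- `src/scwnet/model_io.py` — domain types, GRO-dialect frame I/O
  (via MDAnalysis), reduced state variables, density validation table.
- `src/scwnet/energetics.py` — pair energy decomposition and the
  interaction criterion.
- `src/scwnet/network_build.py` — inner-cube filter, interference
  cylinder, candidate-pair screen, network assembly.
- `src/scwnet/topology.py` — density/degree/PageRank/components and the
  power-law size model.
- `src/scwnet/calibration.py` — λ calibration, curve agreement metrics,
  PCA representative selection.
- `src/scwnet/qtaim.py` — BCP tables, energy densities, interaction
  classes, group comparisons.
- `src/scwnet/synthetic.py` — thermal frames, planted clusters and
  synthetic BCP tables with ground truth.
- `docs/methods.md` — model assumptions, parameter choices and
  limitations.
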