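# dropletkit

Post-simulation analysis of coarse-grained, multi-chain simulations of
aggregating intrinsically disordered proteins (IDPs), built around the
liquid-liquid phase separation (LLPS) of α-synuclein. Given a bead
trajectory of M polymer chains in a periodic box, the package detects
chain clusters and the dense (droplet) and dilute phases, measures droplet
geometry and thermodynamics, residue contact maps, graph-theoretic
connectivity, and sequence-level LLPS propensity — together with a
synthetic-data module that makes every stage verifiable without running
molecular dynamics.

It is aimed at people who run coarse-grained (e.g. Martini-style)
condensate simulations and want the downstream analysis as tested,
reusable library code rather than ad hoc scripts.

## What it computes

**Clusters and phases.** Two chains are bound when their minimum bead-bead
distance (minimum image) is below 0.8 nm. Clusters are connected components
of the contact graph; chains in clusters of ≤ 3 are the *dilute* phase,
aggregates of ≥ 6 chains are the *dense* phase (tetramers/pentamers are
intermediate and excluded from both).

**Droplet geometry.** The mass-weighted gyration tensor
C<sub>αβ</sub> = Σᵢ mᵢ (r<sub>iα</sub> − r<sub>CM,α</sub>)(r<sub>iβ</sub> − r<sub>CM,β</sub>) / Σᵢ mᵢ
with eigenvalues λ₁ ≥ λ₂ ≥ λ₃ gives R<sub>g</sub>² = λ₁+λ₂+λ₃, droplet
ellipsoid semi-axes, per-chain conformation (R<sub>g</sub>, Kabsch RMSD) and
principal-axis orientation angles between neighbouring chains.

**Thermodynamics.** Phase concentrations
c = N / (N<sub>A</sub> V) with the droplet volume
V = (4π/3)√(λ₁λ₂λ₃) (or the uniform-density convention ×5<sup>3/2</sup>);
the excess free energy of chain transfer
ΔG = RT ln(c<sub>dilute</sub>/c<sub>dense</sub>);
and surface tension from thermal shape fluctuations of the droplet
semi-axes, δa = a − R:

γ₂₀ = 5k<sub>B</sub>T / (16π⟨(δa+δb)²⟩),  γ₂₂ = 15k<sub>B</sub>T / (16π⟨(δa−δb)²⟩),

with the pair mean squares averaged over the three unordered axis pairs.

**Graphs.** Each droplet becomes a graph (chains = nodes, contacts = edges);
small-worldness S = (C/C<sub>rand</sub>)/(L/L<sub>rand</sub>) is computed
against a connected Erdős–Rényi G(n, m) null ensemble of the same size.

**Sequence metrics.** Shannon entropy of residue composition and
Kyte–Doolittle hydropathy, with a harness to rank a query sequence against
user-supplied LLPS+/LLPS−/folded datasets.

**Setup arithmetic.** Exact box sizing from a target concentration
a = (N/(N<sub>A</sub>C))<sup>1/3</sup>, crowder and ion counts with exact
electroneutrality, the λ-scaled water–protein Lennard-Jones transform
(σ′ = λσ, ε′ = λε) and the purely repulsive crowder potential
V(r) = 4γε(σ/r)¹².

## Worked example

```python
from dropletkit.synthdata import SynthSpec, gen_droplet_system
from dropletkit.aggregates import assign_frame
from dropletkit.thermo import phase_concentrations, delta_g_transfer
from dropletkit.graphs import ERNullCache, droplet_graph, graph_small_worldness

spec = SynthSpec(n_chains_dense=10, n_chains_dilute=5, seed=42)
system, truth = gen_droplet_system(spec)
frame = assign_frame(system, 0)
print("largest cluster:", frame.largest_cluster_size,
      "| free monomers:", frame.n_free_monomers)

pc = phase_concentrations(system, frame, convention="sqrt-5-lambda")
print(f"c_dense = {pc.c_dense_uM:.0f} uM, c_dilute = {pc.c_dilute_uM:.0f} uM")
print(f"dG_transfer = {delta_g_transfer(pc.c_dilute_uM, pc.c_dense_uM):.2f} kJ/mol")

g = droplet_graph(system, 0, frame.dense_clusters()[0])
sw = graph_small_worldness(g, ERNullCache(ensemble_size=500, seed=0))
print(f"droplet graph: n={sw.n_nodes}, m={sw.n_edges}, C={sw.C:.3f}, "
      f"L={sw.L:.3f}, S={sw.S:.2f}")
```

Output:

```
largest cluster: 10 | free monomers: 5
c_dense = 150665 uM, c_dilute = 535 uM
dG_transfer = -14.54 kJ/mol
droplet graph: n=10, m=14, C=0.433, L=2.333, S=1.52
```

The generator placed 10 chains in one connected droplet and 5 isolated
monomers, and the analysis recovers exactly that partition. The dense phase
is ~280× more concentrated than the dilute phase, so moving a chain out of
the droplet costs free energy (ΔG < 0 for the dense direction), and the
droplet's contact graph is more clustered than a size-matched random graph
at comparable path length (S > 1).

A command-line entry point mirrors the library:

```sh
dropletkit setup --n-chains 50 --conc-um 750 --salt-mm 50   # box + ion counts
dropletkit synth -o demo --n-dense 8 --n-dilute 4           # synthetic GRO
dropletkit aggregates demo.gro                              # cluster summary
dropletkit run config.yaml                                  # full pipeline
```

For example, `dropletkit setup --n-chains 50 --conc-um 750 --salt-mm 50`
prints a box edge of 48.016 nm and exactly 3783 Na⁺ / 3333 Cl⁻ for the
−9 e net charge of the packaged 140-residue α-synuclein sequence.

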