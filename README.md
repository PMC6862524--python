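# aggfold

Analysis of peptide self-association and aggregation-driven folding in
multi-chain trajectories.

Short cationic antimicrobial peptides (AMPs) are often disordered or only
partially folded as isolated monomers in water, yet act on bacterial
membranes as amphipathic α-helices.  One proposed resolution is that the
peptides self-associate in solution *before* reaching the membrane: inside
an aggregate, neighbouring chains mimic the water–membrane interface and
stabilise the folded helix.  `aggfold` implements the complete trajectory
analysis needed to study this mechanism, exercised on the 20-residue
bombinin H2 peptide (`IIGPVLGLVGSALGGLLKKI`, +2 e, 25 % glycine):

* **model** — sequence parsing, composition/charge statistics and the
  hydrophobic / polar / charged residue classification.
* **synthetic** — a kinematic trajectory generator: 27 chains on a 5 nm
  grid in a 15 × 15 × 15 nm³ periodic box (13 mM), with scripted aggregate
  merges, scripted helix-loop-helix → single-helix "snap" transitions,
  rigid-body diffusion and Gaussian positional noise, emitting the exact
  event schedule as a ground-truth ledger.
* **geometry** — Kabsch superposition, RMSF, radius of gyration, and
  minimum-image distances.
* **sasa** — Shrake–Rupley solvent-accessible surface area decomposed by
  residue class, and the polar/hydrophobic ratio σ_p/hphb(t).
* **secstruct** — dihedral-window helix assignment and classification of
  each chain as *single-helix* (the Val5–Lys17 core fully helical),
  *helix-loop-helix* (two helical segments broken at the Gly10–Ser11
  hinge) or *disordered*, plus windowed state occupancy.
* **ensemble** — GROMOS-style greedy conformational clustering (0.3 nm
  cutoff) and Cartesian backbone PCA on the 60 N/Cα/C atoms per chain,
  with eigen-RMSF profiles and projections.
* **aggregation** — contact-graph aggregate detection (chains adjacent
  when any inter-chain atom pair is within 5 Å under periodic boundaries),
  aggregate count / maximum size series, neighbour attribution, and
  per-residue intermolecular contact statistics grouped by state.
* **kinetics** — detection of stable straightening transitions, the folded
  count N_h(t), and the logistic saturation fit

  $$N_h(t) = \frac{h_\mathrm{max}}{1 + e^{-k\,(t - t_{1/2})}},$$

  with asymptote h_max, half-saturation time t_1/2 and rate k (the
  decreasing-exponent convention λ = −k is also reported).

Trajectories are multi-model PDB files (one MODEL per frame, CRYST1 box,
REMARK time stamps); all tables are TSV, all summaries JSON.

## Worked example

Reconstruct a 2 μs, 27-chain scenario in which the chains coalesce into a
single aggregate and nine of them straighten at the transition times
observed in the reference microsecond-scale simulations:

```python
from aggfold import Scenario, generate_trajectory
from aggfold.aggregation import aggregate_series
from aggfold.kinetics import detect_transitions, fit_sigmoid, folded_count, transitions_table
from aggfold.reference import REPORTED_TRANSITION_TIMES_NS
from aggfold.secstruct import state_series
from aggfold.synthetic import MergeEvent, StraightenEvent, default_chain_ids, full_coalescence_events

ids = default_chain_ids(27)
merges = (MergeEvent(15.0, "V", "a"),) + full_coalescence_events(
    tuple(c for c in ids if c not in ("V", "a")), start_ns=100.0, interval_ns=15.0
) + (MergeEvent(480.0, "C", "V"),)
straightens = tuple(
    StraightenEvent(t, c) for c, t in sorted(REPORTED_TRANSITION_TIMES_NS.items())
)
scenario = Scenario(duration_ns=2000.0, merge_events=merges,
                    straighten_events=straightens, noise_sigma_nm=0.0, seed=1)
traj, ledger = generate_trajectory(scenario)

aggs = aggregate_series(traj)
states = state_series(traj)
records = detect_transitions(states, traj=traj)
nh = folded_count(records, traj.times_ns)
params, diag = fit_sigmoid(traj.times_ns, nh)

print(f"aggregates: {aggs.n_aggregates[0]} -> {aggs.n_aggregates[-1]}")
print(f"chains straightened: {nh[-1]} of {traj.n_chains}; "
      f"{nh[traj.nearest_frame(100.0)]} within the first 100 ns")
print(f"sigmoid fit: h_max = {params.h_max:.2f}, "
      f"t_1/2 = {params.t_half_ns:.0f} ns, k = {params.k_per_ns:.4f} /ns")
print(transitions_table(records).head(4).to_string(index=False))
```

prints

```
aggregates: 27 -> 1
chains straightened: 9 of 27; 3 within the first 100 ns
sigmoid fit: h_max = 9.66, t_1/2 = 647 ns, k = 0.0024 /ns
chain_id  time_ns    neighbours  aggregate_size aggregate
       A    903.0             B              27    27-mer
       B    917.0          A, D              27    27-mer
       D    931.0          B, C              27    27-mer
       E    735.0 C, D, F, G, M              27    27-mer
```

Nine of 27 chains end in the single-helix state; three transitions occur
within the first 100 ns (in dimers, while the aggregates are still small);
the fitted half-saturation time of ≈650 ns and asymptote ≈9.7 chains
summarise the saturation of the folding process at one third of the
monomers.

The same pipeline is available from the shell:

```bash
aggfold simulate --config scenario.yaml --seed 1 --out run/
aggfold analyze-aggregation --traj run/trajectory.pdb --out run/analysis/
aggfold analyze-monomer --traj monomer.pdb --out mono/
aggfold report --out run/
```

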