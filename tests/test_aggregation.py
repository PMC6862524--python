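import numpy as np
import pytest

from aggfold.aggregation import (
    aggregate_series,
    chain_contact_graph,
    intermolecular_contacts,
    neighbors_at_time,
    oligomer_name,
)
from aggfold.model import BOMBININ_H2
from aggfold.secstruct import ConformationState, StateSeries, state_series
from aggfold.synthetic import (
    MergeEvent,
    Scenario,
    StraightenEvent,
    default_chain_ids,
    full_coalescence_events,
    generate_trajectory,
)
from aggfold.trajectory import Trajectory

BOX = np.array([15.0, 15.0, 15.0])


def _line_chains(offsets_y):
    """Synthetic chains whose atoms lie on x-parallel lines at given y offsets;
    the closest approach between consecutive chains equals the y spacing."""
    n_res, n_at = 20, 5
    x = np.linspace(3.0, 8.0, n_res * n_at)
    chains = []
    for dy in offsets_y:
        c = np.zeros((n_res, n_at, 3))
        c[..., 0] = x.reshape(n_res, n_at)
        c[..., 1] = 5.0 + dy
        c[..., 2] = 5.0
        chains.append(c)
    return np.stack(chains)


class TestChainContactGraph:
    def test_grid_frame_has_no_contacts(self):
        traj, _ = generate_trajectory(Scenario(duration_ns=0, noise_sigma_nm=0.0))
        adj = chain_contact_graph(traj.frame_coords(0), traj.box_nm, 0.5)
        assert not adj.any()

    def test_pair_within_cutoff_adjacent(self):
        frame = _line_chains([0.0, 0.4])
        adj = chain_contact_graph(frame, BOX, 0.5)
        assert adj[0, 1] and adj[1, 0]

    def test_transitive_component(self):
        # A-B at 0.4, B-C at 0.4, A-C at 0.8: one component of three
        frame = _line_chains([0.0, 0.4, 0.8])
        adj = chain_contact_graph(frame, BOX, 0.5)
        assert adj[0, 1] and adj[1, 2] and not adj[0, 2]
        from aggfold.aggregation import _components

        labels = _components(adj)
        assert len(np.unique(labels)) == 1

    def test_adjacency_matches_27_image_brute_force(self):
        rng = np.random.default_rng(17)
        n_chains, n_res, n_at = 4, 20, 5
        coords = rng.uniform(0, 15, size=(n_chains, n_res, n_at, 3))
        cutoff = 2.0
        adj = chain_contact_graph(coords, BOX, cutoff)
        shifts = np.array(
            [[i, j, k] for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)]
        ) * BOX
        for a in range(n_chains):
            for b in range(a + 1, n_chains):
                pa = coords[a].reshape(-1, 3)
                pb = coords[b].reshape(-1, 3)
                dmin = min(
                    np.sqrt(((pa[:, None] - (pb + s)[None, :]) ** 2).sum(-1)).min()
                    for s in shifts
                )
                assert adj[a, b] == (dmin < cutoff)

    def test_nonpositive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            chain_contact_graph(_line_chains([0.0]), BOX, 0.0)


class TestAggregateSeries:
    def test_no_event_scenario_constant_27(self):
        traj, _ = generate_trajectory(Scenario(duration_ns=5, noise_sigma_nm=0.0))
        aggs = aggregate_series(traj)
        assert np.all(aggs.n_aggregates == 27)
        assert np.all(aggs.max_size == 1)

    def test_merge_only_series_is_monotone(self):
        ids = default_chain_ids(10)
        events = tuple(
            MergeEvent(2.0 + 2 * k, ids[0], ids[k + 1]) for k in range(9)
        )
        sc = Scenario(n_chains=10, duration_ns=25, merge_events=events)
        traj, _ = generate_trajectory(sc)
        aggs = aggregate_series(traj)
        assert np.all(np.diff(aggs.n_aggregates) <= 0)
        assert np.all(np.diff(aggs.max_size) >= 0)

    def test_full_coalescence_ends_in_single_27mer(self):
        events = full_coalescence_events(default_chain_ids(27), 1.0, 1.0)
        sc = Scenario(duration_ns=30, merge_events=events)
        traj, _ = generate_trajectory(sc)
        aggs = aggregate_series(traj)
        assert aggs.n_aggregates[-1] == 1
        assert aggs.max_size[-1] == 27

    def test_partition_sizes_sum_to_chain_count(self):
        ids = default_chain_ids(8)
        events = (MergeEvent(2, ids[0], ids[1]), MergeEvent(4, ids[2], ids[3]))
        traj, _ = generate_trajectory(
            Scenario(n_chains=8, duration_ns=6, merge_events=events)
        )
        aggs = aggregate_series(traj)
        for f in range(traj.n_frames):
            assert sum(len(p) for p in aggs.partition(f)) == 8

    def test_relabelling_invariance(self):
        """Renaming/reordering chains permutes the partition but does not
        change its structure."""
        ids = default_chain_ids(6)
        events = (MergeEvent(1, ids[0], ids[3]), MergeEvent(2, ids[1], ids[5]))
        traj, _ = generate_trajectory(
            Scenario(n_chains=6, duration_ns=4, merge_events=events, noise_sigma_nm=0.0)
        )
        aggs = aggregate_series(traj)
        rng = np.random.default_rng(2)
        perm = rng.permutation(6)
        shuffled = Trajectory(
            traj.sequence,
            tuple(traj.chain_ids[p] for p in perm),
            traj.times_ns,
            traj.box_nm,
            traj.coords_nm[:, perm],
        )
        aggs2 = aggregate_series(shuffled)
        for f in range(traj.n_frames):
            p1 = {frozenset(s) for s in aggs.partition(f)}
            p2 = {frozenset(s) for s in aggs2.partition(f)}
            assert p1 == p2


class TestNeighborsAtTime:
    def test_scripted_dimer_partner(self):
        sc = Scenario(
            duration_ns=30,
            merge_events=(MergeEvent(20, "V", "a"),),
            straighten_events=(StraightenEvent(25, "V"),),
        )
        traj, _ = generate_trajectory(sc)
        assert neighbors_at_time(traj, "V", 25.0) == {"a"}

    def test_isolated_chain_empty(self):
        traj, _ = generate_trajectory(Scenario(duration_ns=2, noise_sigma_nm=0.0))
        assert neighbors_at_time(traj, "A", 0.0) == set()

    def test_chain_inside_full_aggregate(self):
        events = full_coalescence_events(default_chain_ids(27), 1.0, 1.0)
        traj, _ = generate_trajectory(Scenario(duration_ns=28, merge_events=events))
        nbrs = neighbors_at_time(traj, "A", 28.0)
        assert nbrs and nbrs <= set(default_chain_ids(27)) - {"A"}

    def test_unknown_chain_rejected(self):
        traj, _ = generate_trajectory(Scenario(duration_ns=1, n_chains=4))
        with pytest.raises(KeyError):
            neighbors_at_time(traj, "z", 0.0)


def _uniform_states(traj, code):
    return StateSeries(
        traj.chain_ids,
        traj.times_ns,
        np.full((traj.n_frames, traj.n_chains), code, dtype=np.int8),
    )


class TestIntermolecularContacts:
    def test_isolated_monomers_all_zero(self):
        traj, _ = generate_trajectory(
            Scenario(duration_ns=2, n_chains=8, noise_sigma_nm=0.0)
        )
        states = state_series(traj)
        table = intermolecular_contacts(traj, states)
        assert (table["mean_contacts_per_frame"] == 0).all()

    def test_dimer_interface_residues_match_brute_force(self):
        """Interface residues with nonzero mean contacts equal the set found
        by a direct minimum-image distance scan."""
        sc = Scenario(
            duration_ns=4,
            n_chains=2,
            merge_events=(MergeEvent(1, "A", "B"),),
            noise_sigma_nm=0.0,
        )
        traj, _ = generate_trajectory(sc)
        states = _uniform_states(traj, 1)
        table = intermolecular_contacts(traj, states)
        hlh = table[table["state"] == "helix-loop-helix"]
        got = set(hlh[hlh["mean_contacts_per_frame"] > 0]["residue"])

        expected = set()
        cutoff = 0.5
        for f in range(traj.n_frames):
            a = traj.coords_nm[f, 0]
            b = traj.coords_nm[f, 1]
            d = np.sqrt(
                ((a.reshape(-1, 1, 3) - b.reshape(1, -1, 3)) ** 2).sum(-1)
            ).reshape(20, 5, 20, 5)
            ra, rb = np.where((d < cutoff).any(axis=(1, 3)))
            expected |= set(ra + 1) | set(rb + 1)
        assert got == expected
        assert got  # the merged dimer really has an interface

    def test_tighter_packing_gives_higher_state_group_means(self, ideal_helix,
                                                            bent_conformer):
        """Straight chains packed with more interface atoms accumulate higher
        grouped contact means than loosely packed bent chains."""
        centre = np.array([7.5, 7.5, 7.5])
        straight_pair = np.stack(
            [
                ideal_helix.coords_nm + centre,
                ideal_helix.coords_nm + centre + np.array([0.0, 0.55, 0.0]),
            ]
        )
        bent_pair = np.stack(
            [
                bent_conformer.coords_nm + centre + np.array([0.0, 5.0, 0.0]),
                bent_conformer.coords_nm + centre + np.array([0.0, 6.0, 0.0]),
            ]
        )
        frame = np.concatenate([straight_pair, bent_pair])[None]
        traj = Trajectory(
            BOMBININ_H2, ("A", "B", "C", "D"), np.array([0.0]), BOX, frame
        )
        codes = np.array([[2, 2, 1, 1]], dtype=np.int8)
        states = StateSeries(traj.chain_ids, traj.times_ns, codes)
        table = intermolecular_contacts(traj, states)
        by_state = table.groupby("state")["mean_contacts_per_frame"].sum()
        assert by_state["single-helix"] > by_state["helix-loop-helix"] > 0

    def test_misaligned_states_rejected(self):
        traj, _ = generate_trajectory(Scenario(duration_ns=2, n_chains=4))
        bad = StateSeries(("A",), traj.times_ns, np.ones((traj.n_frames, 1), dtype=np.int8))
        with pytest.raises(ValueError, match="aligned"):
            intermolecular_contacts(traj, bad)


class TestOligomerNames:
    @pytest.mark.parametrize(
        "size,name",
        [(1, "Monomer"), (2, "Dimer"), (4, "Tetramer"), (19, "19-mer"), (27, "27-mer")],
    )
    def test_names(self, size, name):
        assert oligomer_name(size) == name

    def test_invalid_size(self):
        with pytest.raises(ValueError):
            oligomer_name(0)
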