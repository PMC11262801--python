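"""Track/label file formats: parsing, partitioning, validation, round-trips."""

import json

import numpy as np
import pytest

import larvaction as la
from larvaction.trackdata_io import LabelSchemaError


@pytest.fixture
def sim_tracks():
    tracks = []
    for i, action in enumerate(("crawl", "bend")):
        track, _ = la.simulate_track(
            la.SimScript(steps=[(action, 5.0)], seed=i, larva_id=i + 1))
        tracks.append(track)
    return tracks


class TestChoreography:
    def test_single_larva_direct_parse(self, tmp_path):
        path = tmp_path / "spine.txt"
        path.write_text(
            "7 0.0 0 0 1 0 2 0 3 0 4 0\n"
            "7 0.1 0 1 1 1 2 1 3 1 4 1\n"
            "7 0.2 0 2 1 2 2 2 3 2 4 2\n"
        )
        tracks = la.read_choreography(path)
        assert len(tracks) == 1
        assert tracks[0].larva_id == 7
        assert tracks[0].spine.shape == (3, 5, 2)
        assert np.allclose(tracks[0].t, [0.0, 0.1, 0.2])

    def test_interleaved_larvae_partition(self, tmp_path):
        path = tmp_path / "spine.txt"
        lines = []
        for k in range(4):
            lines.append(f"1 {k / 10} 0 {k} 1 {k} 2 {k}\n")
            lines.append(f"2 {k / 10} 5 {k} 6 {k} 7 {k}\n")
        path.write_text("".join(lines))
        tracks = la.read_choreography(path)
        assert sorted(tr.larva_id for tr in tracks) == [1, 2]
        assert sum(tr.n_frames for tr in tracks) == 8

    def test_bad_frames_dropped(self, tmp_path):
        path = tmp_path / "spine.txt"
        path.write_text(
            "1 0.0 0 0 1 0 2 0\n"
            "1 0.1 0 0 1 0\n"          # wrong coordinate count
            "1 0.2 0 0 nan 0 2 0\n"    # non-finite
            "1 0.2 0 1 1 1 2 1\n"
            "1 0.2 9 9 9 9 9 9\n"      # duplicate timestamp -> keep first
        )
        (track,) = la.read_choreography(path)
        assert track.n_frames == 2
        assert np.allclose(track.spine[1, 0], [0, 1])

    def test_empty_file(self, tmp_path):
        path = tmp_path / "spine.txt"
        path.write_text("")
        assert la.read_choreography(path) == []

    def test_round_trip_on_simulator_output(self, tmp_path, sim_tracks):
        spine = tmp_path / "spine.txt"
        la.write_choreography(sim_tracks, spine)
        back = la.read_choreography(spine)
        assert len(back) == len(sim_tracks)
        for orig, rt in zip(sim_tracks, back):
            assert rt.larva_id == orig.larva_id
            assert np.allclose(rt.t, orig.t, atol=1e-6)
            assert np.allclose(rt.spine, orig.spine, atol=1e-6)

    def test_reader_output_satisfies_track_invariants(self, tmp_path, sim_tracks):
        spine = tmp_path / "spine.txt"
        la.write_choreography(sim_tracks, spine)
        for track in la.read_choreography(spine):
            track.validate()  # raises on violation


class TestFimtrack:
    def _write_table(self, path, n_larvae=2, n_frames=10, drop=()):
        cols = {}
        for lid in range(n_larvae):
            col = {}
            for k in range(n_frames):
                if (lid, k) in drop:
                    continue
                col[f"time({k})"] = k / 10
                for j in range(1, 4):
                    col[f"spinepoint_x_{j}({k})"] = j + 0.1 * k + lid
                    col[f"spinepoint_y_{j}({k})"] = 0.5 * j
            cols[f"larva({lid})"] = col
        import pandas as pd
        frame = pd.DataFrame(cols)
        frame.index.name = "feature"
        frame.to_csv(path, sep=";")

    def test_direct_parse(self, tmp_path):
        path = tmp_path / "table.csv"
        self._write_table(path)
        tracks = la.read_fimtrack_csv(path)
        assert len(tracks) == 2
        assert all(tr.n_frames == 10 for tr in tracks)
        assert tracks[0].spine.shape == (10, 3, 2)

    def test_missing_frames_leave_gap(self, tmp_path):
        path = tmp_path / "table.csv"
        self._write_table(path, n_larvae=1, drop={(0, 4), (0, 5), (0, 6)})
        (track,) = la.read_fimtrack_csv(path)
        assert track.n_frames == 7
        assert np.diff(track.t).max() == pytest.approx(0.4)

    def test_missing_frame_rate_error(self, tmp_path):
        import pandas as pd
        path = tmp_path / "table.csv"
        frame = pd.DataFrame({"larva(0)": {"spinepoint_x_1(0)": 1.0,
                                           "spinepoint_y_1(0)": 1.0,
                                           "spinepoint_x_2(0)": 2.0,
                                           "spinepoint_y_2(0)": 1.0}})
        frame.index.name = "feature"
        frame.to_csv(path, sep=";")
        with pytest.raises(ValueError, match="frame_rate"):
            la.read_fimtrack_csv(path)

    def test_missing_spine_rows_error_names_group(self, tmp_path):
        import pandas as pd
        path = tmp_path / "table.csv"
        frame = pd.DataFrame({"larva(3)": {"time(0)": 0.0, "area(0)": 1.0}})
        frame.index.name = "feature"
        frame.to_csv(path, sep=";")
        with pytest.raises(ValueError, match="larva"):
            la.read_fimtrack_csv(path)

    def test_round_trip_on_simulator_output(self, tmp_path, sim_tracks):
        path = tmp_path / "table.csv"
        la.write_fimtrack_csv(sim_tracks, path)
        back = la.read_fimtrack_csv(path)
        assert len(back) == len(sim_tracks)
        for orig, rt in zip(sim_tracks, back):
            assert np.allclose(rt.spine, orig.spine, atol=1e-6)
            assert np.allclose(rt.t, orig.t, atol=1e-6)


class TestLabelsJson:
    def _labelset(self):
        return la.LabelSet(
            dictionary=[la.LabelSpec(n, c) for n, c in
                        [("crawl", "#112233"), ("bend", "#445566"),
                         ("back", "#0000ff"), ("hunch", "#ff0000"),
                         ("roll", "#00ff00"), ("stop", "#777777"),
                         ("small_action", "#999999")]],
            assignments={4: [[0], [0, 1], [], [3], [5]]},
            provenance={4: "manual"},
            times={4: np.array([0.0, 0.1, 0.2, 0.3, 0.4])},
        )

    def test_round_trip_bit_identical(self, tmp_path):
        labels = self._labelset()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        la.write_labels_json(labels, p1)
        back = la.read_labels_json(p1)
        assert back.names == labels.names
        assert back.assignments == labels.assignments
        assert back.provenance == labels.provenance
        la.write_labels_json(back, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_assignments(self, tmp_path):
        labels = la.LabelSet(dictionary=[la.LabelSpec("crawl")])
        path = tmp_path / "labels.json"
        la.write_labels_json(labels, path)
        doc = json.loads(path.read_text())
        assert doc["data"] == []
        assert la.read_labels_json(path).assignments == {}

    def test_hand_written_single_tag(self, tmp_path):
        doc = {
            "units": {"t": "s"},
            "metadata": {},
            "labels": {"names": ["crawl", "hunch"], "colors": ["#000000", "#ff0000"]},
            "data": [{"id": 12,
                      "t": [0.0, 0.1, 0.2, 0.3, 0.4],
                      "labels": [[], [], [], ["hunch"], []]}],
        }
        path = tmp_path / "labels.json"
        path.write_text(json.dumps(doc))
        labels = la.read_labels_json(path)
        nonempty = [(lid, k) for lid, vec in labels.assignments.items()
                    for k, step in enumerate(vec) if step]
        assert nonempty == [(12, 3)]
        assert labels.assignments[12][3] == [labels.label_index("hunch")]

    def test_undefined_label_name_rejected(self, tmp_path):
        doc = {"units": {"t": "s"}, "labels": {"names": ["crawl"], "colors": ["#000000"]},
               "data": [{"id": 1, "t": [0.0], "labels": [["wiggle"]]}]}
        path = tmp_path / "labels.json"
        path.write_text(json.dumps(doc))
        with pytest.raises(LabelSchemaError, match="wiggle"):
            la.read_labels_json(path)

    def test_missing_key_reports_json_path(self, tmp_path):
        path = tmp_path / "labels.json"
        path.write_text(json.dumps({"units": {"t": "s"}, "data": []}))
        with pytest.raises(LabelSchemaError, match=r"\$/labels"):
            la.read_labels_json(path)

    def test_unknown_keys_preserved(self, tmp_path):
        labels = self._labelset()
        labels.extra = {"x-custom": {"anything": [1, 2, 3]}}
        path = tmp_path / "labels.json"
        la.write_labels_json(labels, path)
        back = la.read_labels_json(path)
        assert back.extra == {"x-custom": {"anything": [1, 2, 3]}}
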