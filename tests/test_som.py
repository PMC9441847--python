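"""SOM clustering: distance metric, training, assignment, prototypes."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gazenum.heatmap import HeatmapImage, ReducedHeatmap
from gazenum.som import (ClusterAssignment, N_CLUSTERS, SomError, SomModel,
                         SomSchedule, assign, compute_prototypes,
                         heatmap_distance, load_model, quantization_error,
                         recolor, save_model, train_som)

FAST = SomSchedule(phases=(
    type(SomSchedule().phases[0])(epochs=20, lr_start=0.5, lr_end=0.05,
                                  radius_start=2.0, radius_end=1.0),
    type(SomSchedule().phases[0])(epochs=40, lr_start=0.05, lr_end=0.01,
                                  radius_start=1.0, radius_end=0.0),
))


def _blob(cx, cy, shape=(90, 160), sd=8.0, amp=255.0):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return amp * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sd * sd))


small = st.integers(0, 255)


class TestDistance:
    def test_identity(self, rng):
        h = ReducedHeatmap(pixels=rng.integers(0, 256, (90, 160)))
        assert heatmap_distance(h, h) == 0.0

    def test_single_pixel_difference(self):
        a = np.zeros((90, 160))
        b = a.copy()
        b[13, 44] = 10.0
        assert heatmap_distance(a, b) == pytest.approx(10.0)

    def test_dimension_mismatch(self):
        with pytest.raises(SomError):
            heatmap_distance(np.zeros((4, 4)), np.zeros((5, 4)))

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(data=st.data(), h=st.integers(2, 8), w=st.integers(2, 8))
    def test_matches_bruteforce_summation(self, data, h, w):
        """d equals an independent nested-loop sum of squared differences."""
        a = data.draw(st.lists(st.lists(small, min_size=w, max_size=w),
                               min_size=h, max_size=h))
        b = data.draw(st.lists(st.lists(small, min_size=w, max_size=w),
                               min_size=h, max_size=h))
        acc = 0.0
        for i in range(h):
            for j in range(w):
                acc += (a[i][j] - b[i][j]) ** 2
        assert heatmap_distance(np.array(a, float), np.array(b, float)) \
            == pytest.approx(acc ** 0.5, rel=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(data=st.data())
    def test_metric_properties(self, data):
        """Non-negativity, symmetry, triangle inequality on random triples."""
        mk = st.lists(st.lists(small, min_size=5, max_size=5),
                      min_size=4, max_size=4)
        a, b, c = (np.array(data.draw(mk), float) for _ in range(3))
        dab, dba = heatmap_distance(a, b), heatmap_distance(b, a)
        assert dab >= 0 and dab == dba
        assert heatmap_distance(a, c) <= dab + heatmap_distance(b, c) + 1e-9
        assert (heatmap_distance(a, a) == 0) and \
            (dab > 0) == (not np.array_equal(a, b))


class TestTraining:
    def test_identical_inputs_attract_all_prototypes(self, rng):
        h = rng.integers(0, 256, (90, 160)).astype(float)
        model = train_som([h] * 10, FAST, seed=3)
        for k in range(N_CLUSTERS):
            assert np.abs(model.prototype_image(k) - h).max() < 1.0
        assert quantization_error(model, [h] * 10) < 1.0

    def test_seeded_determinism(self, rng):
        inputs = [rng.integers(0, 256, (90, 160)).astype(float)
                  for _ in range(12)]
        m1 = train_som(inputs, FAST, seed=9)
        m2 = train_som(inputs, FAST, seed=9)
        assert np.array_equal(m1.prototypes, m2.prototypes)

    def test_two_populations_match_bruteforce_partition(self, rng):
        """SOM separation agrees >= 95% with nearest-true-mean assignment."""
        pop_a = [_blob(40, 30) + rng.normal(0, 6, (90, 160))
                 for _ in range(20)]
        pop_b = [_blob(120, 60) + rng.normal(0, 6, (90, 160))
                 for _ in range(20)]
        inputs = pop_a + pop_b
        mean_a = np.mean(pop_a, axis=0).ravel()
        mean_b = np.mean(pop_b, axis=0).ravel()
        model = train_som(inputs, FAST, seed=5)
        asg = assign(model, inputs)
        # merge SOM nodes by nearest population mean
        node_side = np.array([
            np.linalg.norm(p - mean_a) > np.linalg.norm(p - mean_b)
            for p in model.prototypes])
        som_side = node_side[asg.cluster_of]
        true_side = np.array([
            np.linalg.norm(x.ravel() - mean_a) > np.linalg.norm(x.ravel() - mean_b)
            for x in inputs])
        assert (som_side == true_side).mean() >= 0.95

    def test_quantization_error_improves_over_initialization(self, rng):
        inputs = [_blob(40 + 80 * (i % 2), 45) + rng.normal(0, 10, (90, 160))
                  for i in range(14)]
        seed = 21
        model = train_som(inputs, FAST, seed=seed)
        # reconstruct the seeded initial prototypes the same way training does
        X = np.stack([x.ravel() for x in inputs])
        init_rng = np.random.default_rng(seed)
        w0 = X.mean(axis=0)[None, :] + init_rng.normal(
            0.0, 0.05 * X.std(), size=(N_CLUSTERS, X.shape[1]))
        assert quantization_error(model, inputs) <= \
            quantization_error(w0, inputs)

    def test_empty_input_rejected(self):
        with pytest.raises(SomError):
            train_som([], FAST, seed=0)


class TestAssign:
    def test_input_equal_to_prototype_lands_there(self, rng):
        inputs = [rng.integers(0, 256, (90, 160)).astype(float)
                  for _ in range(8)]
        model = train_som(inputs, FAST, seed=2)
        probe = model.prototype_image(3)
        assert assign(model, [probe]).cluster_of[0] == 3

    def test_partition_and_group_counts(self, rng):
        inputs = [rng.integers(0, 256, (90, 160)).astype(float)
                  for _ in range(15)]
        labels = ["a"] * 7 + ["b"] * 8
        model = train_som(inputs, FAST, seed=4)
        asg = assign(model, inputs, group_labels=labels)
        assert asg.counts.sum() == 15
        gc = asg.group_counts()
        assert gc["a"].sum() == 7 and gc["b"].sum() == 8
        # counting oracle: direct tally
        for g in ("a", "b"):
            for k in range(N_CLUSTERS):
                direct = sum(1 for i in range(15)
                             if labels[i] == g and asg.cluster_of[i] == k)
                assert gc[g][k] == direct

    def test_ties_break_to_lowest_index(self):
        proto = np.tile(np.arange(6, dtype=float)[:, None], (1, 20))
        proto[4] = proto[1]  # duplicate prototype
        model = SomModel(prototypes=proto, input_shape=(4, 5),
                         schedule=FAST, seed=0)
        x = proto[1].reshape(4, 5)
        assert assign(model, [x]).cluster_of[0] == 1

    def test_idempotent_and_order_independent(self, rng):
        inputs = [rng.integers(0, 256, (90, 160)).astype(float)
                  for _ in range(10)]
        model = train_som(inputs, FAST, seed=6)
        a = assign(model, inputs).cluster_of
        b = assign(model, inputs).cluster_of
        rev = assign(model, inputs[::-1]).cluster_of[::-1]
        assert np.array_equal(a, b) and np.array_equal(a, rev)


class TestPrototypes:
    @staticmethod
    def _img(arr):
        return HeatmapImage(pixels=np.asarray(arr, dtype=np.uint8))

    def test_mean_of_identical_members_is_the_member(self):
        px = np.full((6, 8, 3), 77, np.uint8)
        asg = ClusterAssignment(cluster_of=np.zeros(3, int),
                                group_labels=["g"] * 3, trial_index=[0, 1, 2])
        protos = compute_prototypes(asg, [self._img(px)] * 3)
        assert len(protos) == 1
        assert np.array_equal(protos[0].pixels, px.astype(float))

    def test_two_member_mean(self):
        a = np.full((4, 4, 3), 10, np.uint8)
        b = np.full((4, 4, 3), 30, np.uint8)
        asg = ClusterAssignment(cluster_of=np.array([2, 2]),
                                group_labels=["g", "g"], trial_index=[0, 1])
        protos = compute_prototypes(asg, [self._img(a), self._img(b)])
        assert protos[0].cluster_index == 2
        assert (protos[0].pixels == 20.0).all()

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(data=st.data(), n=st.integers(1, 5))
    def test_matches_bruteforce_pixel_mean(self, data, n):
        """Prototype equals a nested-loop per-pixel mean of its members."""
        imgs = [np.array(data.draw(
            st.lists(st.lists(st.lists(small, min_size=3, max_size=3),
                              min_size=2, max_size=2),
                     min_size=2, max_size=2)), dtype=np.uint8)
            for _ in range(n)]
        asg = ClusterAssignment(cluster_of=np.ones(n, int) * 5,
                                group_labels=["g"] * n,
                                trial_index=list(range(n)))
        proto = compute_prototypes(asg, [self._img(im) for im in imgs])[0]
        for y in range(2):
            for x in range(2):
                for ch in range(3):
                    expect = sum(float(im[y, x, ch]) for im in imgs) / n
                    assert proto.pixels[y, x, ch] == pytest.approx(expect)

    def test_empty_clusters_yield_no_prototype(self):
        asg = ClusterAssignment(cluster_of=np.array([0, 0, 3]),
                                group_labels=["g"] * 3, trial_index=[0, 1, 2])
        protos = compute_prototypes(
            asg, [self._img(np.zeros((2, 2, 3)))] * 3)
        assert [p.cluster_index for p in protos] == [0, 3]

    def test_missing_fullsize_heatmap_is_error(self):
        asg = ClusterAssignment(cluster_of=np.array([0, 1]),
                                group_labels=["g", "g"], trial_index=[0, 1])
        with pytest.raises(SomError):
            compute_prototypes(asg, [self._img(np.zeros((2, 2, 3)))])


class TestRecolor:
    def test_green_becomes_blue(self):
        from gazenum.som import ClusterPrototype
        px = np.zeros((2, 2, 3))
        px[0, 0] = (0, 255, 0)
        p = recolor(ClusterPrototype(cluster_index=0, pixels=px,
                                     member_count=1))
        assert tuple(p.pixels[0, 0]) == (0, 0, 255)
        assert tuple(p.pixels[1, 1]) == (0, 0, 0)  # black stays black

    def test_red_channel_untouched_green_zeroed(self, rng):
        from gazenum.som import ClusterPrototype
        px = rng.integers(0, 256, (5, 7, 3)).astype(float)
        p = recolor(ClusterPrototype(cluster_index=1, pixels=px,
                                     member_count=2))
        assert np.array_equal(p.pixels[..., 0], px[..., 0])
        assert (p.pixels[..., 1] == 0).all()
        assert np.array_equal(p.pixels[..., 2], px[..., 1])


def test_model_round_trip(tmp_path, rng):
    inputs = [rng.integers(0, 256, (90, 160)).astype(float) for _ in range(8)]
    model = train_som(inputs, FAST, seed=8)
    save_model(model, tmp_path / "som")
    back = load_model(tmp_path / "som")
    assert np.array_equal(back.prototypes, model.prototypes)
    assert back.input_shape == model.input_shape
    assert back.schedule == model.schedule
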