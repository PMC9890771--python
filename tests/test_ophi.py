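"""Order-preserving homomorphic index scheme: keys, noise, homomorphism,
comparison, sorting, instance encryption."""

import json

import numpy as np
import pytest

from ppddp.model import DDPInstance, MalformedInstanceError
from ppddp.ophi import (
    KEY_MAGNITUDE_BOUND,
    DepthExhaustedError,
    EncryptedInstance,
    KeyVector,
    NoiseBudget,
    Order,
    add,
    compare,
    encrypt,
    encrypt_instance,
    instance_budget,
    keygen,
    permute,
    sort_ciphertexts,
    subtract,
)


class TestKeygen:
    def test_deterministic_under_seed(self):
        k1 = keygen(3, rng=np.random.default_rng(7))
        k2 = keygen(3, rng=np.random.default_rng(7))
        assert k1 == k2

    def test_components_in_range(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            key = keygen(4, rng=rng)
            assert all(0 < k <= KEY_MAGNITUDE_BOUND for k in key.k)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            keygen(1)

    def test_key_vector_invariants_enforced(self):
        with pytest.raises(ValueError):
            KeyVector(k=(2.0, -1.0, 3.0))
        with pytest.raises(ValueError):
            KeyVector(k=(2.0, 3.0, 2000.0))


class TestEncrypt:
    def test_forced_noise_exact_arithmetic(self, forced_key):
        key, budget = forced_key
        ct = encrypt(key, 10, budget, np.random.default_rng(0), noise=[0.2, 0.3])
        assert ct.c == pytest.approx((20.2, 30.3, 2.5))

    def test_zero_plaintext_is_noise_only(self, forced_key):
        key, budget = forced_key
        ct = encrypt(key, 0, budget, np.random.default_rng(1))
        k = np.asarray(key.k[:-1])
        assert np.all(np.asarray(ct.c[:-1]) < k * budget.p_min)

    def test_probabilistic_encryptions_differ(self, forced_key):
        key, budget = forced_key
        rng = np.random.default_rng(2)
        a = encrypt(key, 5, budget, rng)
        b = encrypt(key, 5, budget, rng)
        assert all(x != y for x, y in zip(a.c, b.c))

    def test_fresh_ciphertext_bounds(self):
        # k_i*m < c_i < k_i*(m + p_min) on the informative coordinates
        rng = np.random.default_rng(3)
        for _ in range(200):
            key = keygen(3, rng=rng)
            budget = NoiseBudget(p_min=1.0, L_max=4).resolved(key)
            m = int(rng.integers(0, 10**6))
            ct = encrypt(key, m, budget, rng)
            k = np.asarray(key.k[:-1])
            c = np.asarray(ct.c[:-1])
            assert np.all(k * m < c) or m == 0
            assert np.all(c < k * (m + budget.p_min))
            assert ct.c[-1] > 0


class TestHomomorphism:
    def test_add_exact(self, forced_key):
        key, budget = forced_key
        rng = np.random.default_rng(0)
        x = encrypt(key, 10, budget, rng, noise=[0.2, 0.3])
        y = encrypt(key, 5, budget, rng, noise=[0.1, 0.1])
        z = add(x, y)
        assert z.c == pytest.approx((30.3, 45.4, 3.5))
        # identical to a fresh encryption of 15 with the combined noise
        direct = encrypt(key, 15, NoiseBudget(p_min=1, L_max=2, R_bound=2.0),
                         rng, noise=[0.3, 0.4])
        assert z.c == pytest.approx(direct.c)

    def test_subtract_exact(self, forced_key):
        key, budget = forced_key
        rng = np.random.default_rng(0)
        x = encrypt(key, 15, NoiseBudget(p_min=1, L_max=2, R_bound=2.0), rng, noise=[0.3, 0.4])
        y = encrypt(key, 5, budget, rng, noise=[0.1, 0.1])
        z = subtract(x, y)
        # tail = k_n*(R_x - R_y) = 5*(0.7 - 0.2)
        assert z.c == pytest.approx((20.2, 30.3, 2.5))

    def test_self_subtraction_cancels_exactly(self, forced_key):
        key, budget = forced_key
        x = encrypt(key, 9, budget, np.random.default_rng(5))
        z = subtract(x, x)
        assert z.c[:-1] == (0.0, 0.0)

    def test_depth_budget_enforced(self, forced_key):
        key, budget = forced_key  # L_max = 2
        rng = np.random.default_rng(6)
        x = encrypt(key, 1, budget, rng)
        y = add(x, encrypt(key, 2, budget, rng))
        with pytest.raises(DepthExhaustedError):
            add(y, y)

    def test_homomorphism_identity_random(self):
        # add(Enc(m1), Enc(m2)) == Enc(m1+m2) with noise R1+R2, componentwise
        rng = np.random.default_rng(7)
        for _ in range(300):
            key = keygen(3, rng=rng)
            budget = NoiseBudget(p_min=1.0, L_max=2).resolved(key)
            m1, m2 = (int(v) for v in rng.integers(0, 10**5, 2))
            r1 = np.full(2, 1e-4 * budget.R_bound)
            r2 = np.full(2, 2e-4 * budget.R_bound)
            z = add(encrypt(key, m1, budget, rng, noise=r1),
                    encrypt(key, m2, budget, rng, noise=r2))
            w = encrypt(key, m1 + m2, NoiseBudget(p_min=1, L_max=2, R_bound=budget.R_bound * 2),
                        rng, noise=r1 + r2)
            np.testing.assert_allclose(z.c, w.c, rtol=1e-9)


class TestCompare:
    def test_distinct_plaintexts_always_ordered(self):
        rng = np.random.default_rng(8)
        for _ in range(1000):
            key = keygen(3, rng=rng)
            budget = NoiseBudget(p_min=1.0, L_max=4).resolved(key)
            m2 = int(rng.integers(0, 10**6))
            m1 = m2 + int(rng.integers(1, 100))
            assert compare(encrypt(key, m1, budget, rng), encrypt(key, m2, budget, rng)) is Order.GREATER

    def test_reflexive_comparison_is_tie(self, forced_key):
        key, budget = forced_key
        x = encrypt(key, 3, budget, np.random.default_rng(9))
        assert compare(x, x) is Order.INDISTINGUISHABLE

    def test_accumulated_sums_stay_ordered(self):
        # sums of L <= L_max ciphertexts with distinct totals compare correctly
        rng = np.random.default_rng(10)
        for _ in range(200):
            key = keygen(3, rng=rng)
            L = int(rng.integers(2, 9))
            budget = NoiseBudget(p_min=1.0, L_max=L).resolved(key)
            a = rng.integers(1, 1000, L)
            b = rng.integers(1, 1000, L)
            if a.sum() == b.sum():
                continue
            sa = encrypt(key, int(a[0]), budget, rng)
            sb = encrypt(key, int(b[0]), budget, rng)
            for v in a[1:]:
                sa = add(sa, encrypt(key, int(v), budget, rng))
            for v in b[1:]:
                sb = add(sb, encrypt(key, int(v), budget, rng))
            expect = Order.GREATER if a.sum() > b.sum() else Order.LESS
            assert compare(sa, sb) is expect

    def test_equal_plaintexts_tie_under_noise_gap(self, forced_key):
        key, _ = forced_key
        budget = NoiseBudget(p_min=1.0, L_max=2).resolved(key)
        rng = np.random.default_rng(11)
        x = encrypt(key, 7, budget, rng)
        y = encrypt(key, 7, budget, rng)
        tie_gap = min(key.k) / 2
        assert compare(x, y, tie_gap=tie_gap) is Order.INDISTINGUISHABLE


class TestSortAndPermute:
    def _encrypt_list(self, values, seed=0):
        rng = np.random.default_rng(seed)
        key = keygen(3, rng=rng)
        budget = NoiseBudget(p_min=1.0, L_max=4).resolved(key)
        return key, [encrypt(key, v, budget, rng) for v in values]

    def test_sort_recovers_plaintext_order(self):
        rng = np.random.default_rng(12)
        for trial in range(100):
            values = [int(v) for v in rng.choice(10**4, size=8, replace=False)]
            _, cts = self._encrypt_list(values, seed=trial)
            perm, srt = sort_ciphertexts(cts)
            assert [values[i] for i in perm] == sorted(values)

    def test_sorted_input_gives_identity_permutation(self):
        _, cts = self._encrypt_list([1, 5, 9, 12])
        perm, _ = sort_ciphertexts(cts)
        assert perm == (0, 1, 2, 3)

    def test_duplicates_stay_in_input_order(self):
        key, cts = self._encrypt_list([4, 2, 4, 1, 4])
        perm, _ = sort_ciphertexts(cts, tie_gap=min(key.k) / 2)
        assert perm == (3, 1, 0, 2, 4)

    def test_permute_round_trip(self):
        _, cts = self._encrypt_list([3, 1, 2])
        perm = [2, 0, 1]
        inv = [1, 2, 0]
        assert permute(permute(cts, perm), inv) == cts

    def test_non_bijective_perm_rejected(self):
        _, cts = self._encrypt_list([3, 1, 2])
        with pytest.raises(ValueError):
            permute(cts, [0, 0, 1])


class TestEncryptInstance:
    def test_counts_and_public_params(self, toy_instance, toy_encrypted):
        _, enc = toy_encrypted
        assert (enc.p, enc.q, enc.t) == (2, 2, 3)
        assert enc.n == 3 and enc.threshold > 0

    def test_invalid_instance_refused(self):
        inst = DDPInstance(A=[1, 4], B=[2, 3], C=[1, 1, 4])
        with pytest.raises(MalformedInstanceError):
            encrypt_instance(keygen(3, rng=np.random.default_rng(0)), inst)

    def test_sorted_C_encrypts_to_sorted_ciphertexts(self, toy_encrypted):
        key, enc = toy_encrypted
        perm, _ = sort_ciphertexts(list(enc.C_c), tie_gap=min(key.k) / 2)
        assert perm == tuple(range(enc.t))

    def test_file_round_trip(self, toy_encrypted, tmp_path):
        _, enc = toy_encrypted
        f = tmp_path / "enc.json"
        enc.to_json(f)
        back = EncryptedInstance.from_json(f)
        assert (back.p, back.q, back.t, back.n) == (enc.p, enc.q, enc.t, enc.n)
        np.testing.assert_allclose(back.matrix("A"), enc.matrix("A"), rtol=1e-11)

    def test_malformed_file_raises_schema_error(self, toy_encrypted, tmp_path):
        _, enc = toy_encrypted
        f = tmp_path / "enc.json"
        enc.to_json(f)
        d = json.loads(f.read_text())
        d["A_c"] = d["A_c"][:-1]  # tamper with the ciphertext count
        f.write_text(json.dumps(d))
        with pytest.raises(MalformedInstanceError):
            EncryptedInstance.from_json(f)

    def test_budget_formula(self, toy_instance):
        key = keygen(3, rng=np.random.default_rng(1))
        b = instance_budget(key, toy_instance)
        assert b.L_max == 2 * (toy_instance.p + toy_instance.q)
        assert b.R_bound == pytest.approx(min(key.k) * b.p_min / (2 * b.L_max))
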