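"""Mode registry, plugin contract and descriptor-space enumeration."""

import textwrap

import pytest

from pseaac.errors import ConfigurationError, PluginContractError
from pseaac.registry import (
    BUILTIN_MODE_NAMES,
    default_resources,
    enumerate_descriptor_space,
    register_builtin_modes,
    register_plugin,
)
from pseaac.synthetic import synth_pssm, synth_proteins


class TestBuiltins:
    def test_thirteen_modes(self):
        registry = register_builtin_modes()
        assert len(registry) == 13
        assert tuple(registry.names()) == BUILTIN_MODE_NAMES

    def test_pseaac1_dim_is_20_plus_lambda(self):
        spec = register_builtin_modes().get("pseaac1")
        res = default_resources()
        assert spec.dim(spec.resolve_params({"lam": 7}), res) == 27
        assert spec.dim(spec.defaults(), res) == 50

    def test_duplicate_registration_rejected(self):
        registry = register_builtin_modes()
        with pytest.raises(ConfigurationError, match="aac"):
            registry.register(registry.get("aac"))

    def test_unknown_mode_lookup(self):
        with pytest.raises(ConfigurationError, match="unknown mode"):
            register_builtin_modes().get("nope")

    def test_unknown_parameter_rejected(self):
        spec = register_builtin_modes().get("pseaac1")
        with pytest.raises(ConfigurationError, match="lambda_"):
            spec.resolve_params({"lambda_": 5})

    def test_dim_contract_all_modes_fuzzed(self):
        """dim(params) equals the emitted vector length for every builtin
        mode on 50 random sequences."""
        registry = register_builtin_modes()
        res = default_resources()
        records = synth_proteins(seed=5, n=50, length_range=(70, 150))
        from pseaac.synthetic import synth_annotation_map

        amap = synth_annotation_map(6, [r.id for r in records], n_terms=25)
        res.annotation_maps = {"go": amap, "fdom": amap}
        res.pssms = {r.id: synth_pssm(10 + i, r) for i, r in enumerate(records)}
        params = {"pseaac1": {"lam": 10}, "pseaac2": {"lam": 10}}
        for name in registry.names():
            spec = registry.get(name)
            for rec in records:
                vec = registry.compute_checked(
                    name, rec, params.get(name), res
                )
                assert len(vec) == spec.dim(
                    spec.resolve_params(params.get(name)), res
                )


class TestPlugins:
    PLUGIN_OK = textwrap.dedent(
        """
        import numpy as np
        from pseaac.registry import ModeSpec
        from pseaac.vector import DescriptorVector

        MODE = ModeSpec(
            name="seqlen",
            description="sequence length as a single feature",
            params={},
            requires=(),
            dim=lambda p, r: 1,
            compute=lambda rec, p, r: DescriptorVector(
                "seqlen", ("LEN",), np.array([float(rec.length)])
            ),
        )
        """
    )

    def test_toy_plugin_runs_like_builtin(self, tmp_path):
        path = tmp_path / "seqlen_plugin.py"
        path.write_text(self.PLUGIN_OK)
        registry = register_builtin_modes()
        register_plugin(registry, path)
        assert "seqlen" in registry
        rec = synth_proteins(1, 1, (30, 30))[0]
        vec = registry.compute_checked("seqlen", rec, None, default_resources())
        assert vec.values.tolist() == [30.0]

    def test_missing_contract_members(self, tmp_path):
        path = tmp_path / "bad.py"
        path.write_text("MODE = object()\n")
        registry = register_builtin_modes()
        with pytest.raises(PluginContractError, match="name"):
            register_plugin(registry, path)
        assert len(registry) == 13  # registry untouched

    def test_no_mode_export(self, tmp_path):
        path = tmp_path / "empty.py"
        path.write_text("x = 1\n")
        with pytest.raises(PluginContractError, match="MODE"):
            register_plugin(register_builtin_modes(), path)

    def test_name_collision_with_builtin(self, tmp_path):
        path = tmp_path / "clash.py"
        path.write_text(self.PLUGIN_OK.replace('"seqlen"', '"aac"'))
        with pytest.raises(ConfigurationError, match="aac"):
            register_plugin(register_builtin_modes(), path)

    def test_dim_mismatch_flagged_at_runtime(self, tmp_path):
        path = tmp_path / "liar.py"
        path.write_text(self.PLUGIN_OK.replace("dim=lambda p, r: 1", "dim=lambda p, r: 2"))
        registry = register_builtin_modes()
        register_plugin(registry, path)
        rec = synth_proteins(1, 1, (30, 30))[0]
        with pytest.raises(PluginContractError, match="seqlen"):
            registry.compute_checked("seqlen", rec, None, default_resources())


class TestEnumeration:
    def test_fixed_mode_contributions(self):
        # aac + dpc + tpc alone: 20 + 400 + 8000
        assert enumerate_descriptor_space(0) >= 8420

    def test_autocorrelation_product_rule(self):
        # 3 families x 544 properties x 30 lags
        with_props = enumerate_descriptor_space(544)
        without = enumerate_descriptor_space(0)
        assert with_props - without == 3 * 544 * 30

    def test_exceeds_20000_with_544_properties(self):
        assert enumerate_descriptor_space(544) >= 20000

    def test_annotation_universes_add_linearly(self):
        base = enumerate_descriptor_space(3)
        assert enumerate_descriptor_space(3, go_terms=100, fdom_terms=50) == base + 150
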