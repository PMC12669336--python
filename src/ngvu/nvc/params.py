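"""Registry loader for the NVC/wall parameter defaults."""

from ..synapse.params import ParamRegistry, load_params


def load_nvc_params(overrides: dict | None = None) -> ParamRegistry:
    return load_params(package="ngvu.nvc", overrides=overrides)
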