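"""Exception hierarchy.

``ConfigError``     — invalid configuration (bad group parameters, paths, alpha).
``GenerationError`` — feasible-looking configuration whose daily targets cannot
                      be realised as an event stream (names the violated
                      constraint).
``ValidationError`` — malformed input data (unordered strides, missing hours,
                      missing mandatory columns, out-of-scale scores).
"""


class GaitwatchError(Exception):
    pass


class ConfigError(GaitwatchError):
    pass


class GenerationError(GaitwatchError):
    pass


class ValidationError(GaitwatchError):
    pass
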