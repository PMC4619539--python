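VERSION = "0.1.0"


def version_header() -> str:
    return f"mcrkit v{VERSION}"
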