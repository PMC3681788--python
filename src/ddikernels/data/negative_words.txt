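no
not
neither
fail
fail to
fails to
failed
failed to
failure
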