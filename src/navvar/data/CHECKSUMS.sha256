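2c8ce7878ff9c3e8732c5e5f9a0cab5f416bc7881242d7eb980fa1164be2d00e  scn5a_topology.tsv
3912987182e035bf05323bf7f0f36a0b2244fc658b0546bca23432b4d4c5981c  aa_properties.tsv
88a16c9c6fef032c7532757c6dbc7da24c295c3778705fef6cbd2392ee7c2e7e  grantham.tsv
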