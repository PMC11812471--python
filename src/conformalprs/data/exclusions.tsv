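rsid	reason
rs187328863	low coverage in diagnostic genotyping panel
rs114092250	low coverage in diagnostic genotyping panel
rs10781182	low coverage in diagnostic genotyping panel
rs67538026	low coverage in diagnostic genotyping panel
rs201459901	low coverage in diagnostic genotyping panel
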