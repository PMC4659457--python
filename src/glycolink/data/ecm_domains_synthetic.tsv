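# SYNTHETIC ECM interaction-domain fixture map (triple-helical coordinates,
# inclusive 1-based intervals). The published interaction-domain map is not
# reproduced here: these intervals encode only the qualitative containment of
# the favourable cross-link sites by their reported binding partners, plus an
# MMP1 interval placed two residues past site 17's lysine so the site
# annotates as proximal, not overlapping. Supply a real map in this format
# (name <TAB> chain_scope <TAB> helical_start <TAB> helical_end <TAB> source_tag)
# for production use.
heat shock protein 47	any	80	95	synthetic-fixture
heparan sulphate	any	82	93	synthetic-fixture
alpha1beta1 integrin	any	85	92	synthetic-fixture
alpha2beta1 integrin	any	84	94	synthetic-fixture
enzyme mediated mature cross-link	any	87	90	synthetic-fixture
heat shock protein 47	any	352	365	synthetic-fixture
guanidine extracted decorin	any	355	363	synthetic-fixture
phosphophoryn	any	575	590	synthetic-fixture
alpha2beta1 integrin	any	783	795	synthetic-fixture
heat shock protein 47	any	785	792	synthetic-fixture
Matrix Metalloproteinase 1	any	793	800	synthetic-fixture
dermatan sulphate	any	882	890	synthetic-fixture
interleukin-2	any	880	935	synthetic-fixture
heparin	any	920	930	synthetic-fixture
amyloid precursor protein	any	922	929	synthetic-fixture
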