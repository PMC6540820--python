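species	subfamily	accession	genome_length_mb	nesting_habitat	diet	n_eves
Acromyrmex echinatior	Myrmicinae	GCF_000204515.1	295.945	Ground/arboreal	Fungus	23
Atta cephalotes	Myrmicinae	GCF_000143395.1	317.672	Ground	Fungus	11
Atta colombica	Myrmicinae	GCF_001594045.1	291.258	Ground	Fungus	10
Camponotus floridanus	Formicinae	GCF_000147175.1	232.685	Arboreal	Generalist	11
Cyphomyrmex costatus	Myrmicinae	GCF_001594065.1	300.317	Ground	Fungus	68
Dinoponera quadriceps	Ponerinae	GCF_001313825.1	259.666	Ground	Predatory	13
Harpegnathos saltator	Ponerinae	GCF_000147195.1	294.466	Ground	Predatory	17
Lasius niger	Formicinae	GCA_001045655.1	236.236	Ground	Generalist	2
Linepithema humile	Dolichodirinae	GCF_000217595.1	219.501	Ground/arboreal	Generalist	19
Monomorium pharaonis	Myrmicinae	GCF_000980195.1	257.977	Ground	Generalist	13
Ooceraea biroi	Dorylinae	GCF_000611835.1	212.826	Ground	Predatory	11
Pogonomyrmex barbatus	Myrmicinae	GCF_000187915.1	235.646	Ground	Herbivore	42
Pseudomyrmex gracilis	Pseudomyrmicinae	GCF_002006095.1	282.776	Arboreal	Generalist	52
Solenopsis invicta	Myrmicinae	GCF_000188075.2	396.025	Ground	Generalist	18
Trachymyrmex cornetzi	Myrmicinae	GCF_001594075.1	369.438	Ground	Fungus	39
Trachymyrmex septentrionalis	Myrmicinae	GCF_001594115.1	291.747	Ground	Fungus	26
Trachymyrmex zeteki	Myrmicinae	GCF_001594055.1	267.973	Ground	Fungus	15
Vollenhovia emeryi	Myrmicinae	GCF_000949405.1	287.901	Ground	Predatory	31
Wasmannia auropunctata	Myrmicinae	GCF_000956235.1	324.12	Ground/arboreal	Generalist	13
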