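species_id	binomial	common_name	clade_tags
Hsap	Homo sapiens	Human	tetrapod,vertebrate
Ptro	Pan troglodytes	Chimpanzee	tetrapod,vertebrate
Ggor	Gorilla gorilla	Gorilla	tetrapod,vertebrate
Pabe	Pongo abelii	Orangutan	tetrapod,vertebrate
Mmul	Macaca mulatta	Macaque	tetrapod,vertebrate
Cjac	Callithrix jacchus	Marmoset	tetrapod,vertebrate
Mmus	Mus musculus	Mouse	tetrapod,vertebrate
Rnor	Rattus norvegicus	Rat	tetrapod,vertebrate
Ocun	Oryctolagus cuniculus	Rabbit	tetrapod,vertebrate
Cfam	Canis familiaris	Dog	tetrapod,vertebrate
Fcat	Felis catus	Cat	tetrapod,vertebrate
Ecab	Equus caballus	Horse	tetrapod,vertebrate
Btau	Bos taurus	Cow	tetrapod,vertebrate
Mluc	Myotis lucifugus	Microbat	tetrapod,vertebrate
Pvam	Pteropus vampyrus	Megabat	tetrapod,vertebrate
Eeur	Erinaceus europaeus	Hedgehog	tetrapod,vertebrate
Lafr	Loxodonta africana	Elephant	tetrapod,vertebrate
Dnov	Dasypus novemcinctus	Armadillo	tetrapod,vertebrate
Mdom	Monodelphis domestica	Opossum	tetrapod,vertebrate
Oana	Ornithorhynchus anatinus	Platypus	tetrapod,vertebrate
Ggal	Gallus gallus	Chicken	tetrapod,vertebrate
Tgut	Taeniopygia guttata	Zebra finch	tetrapod,vertebrate
Psin	Pelodiscus sinensis	Chinese softshell turtle	tetrapod,vertebrate
Acar	Anolis carolinensis	Lizard	tetrapod,vertebrate
Xtro	Xenopus tropicalis	Frog	tetrapod,vertebrate
Drer	Danio rerio	Zebrafish	teleost,vertebrate
Trub	Takifugu rubripes	Fugu	teleost,vertebrate
Tnig	Tetraodon nigroviridis	Tetraodon	teleost,vertebrate
Gacu	Gasterosteus aculeatus	Stickleback	teleost,vertebrate
Olat	Oryzias latipes	Medaka	teleost,vertebrate
Bflo	Branchiostoma floridae	Amphioxus	invertebrate,chordate-invertebrate
Cint	Ciona intestinalis	Ascidian	invertebrate,chordate-invertebrate
Csav	Ciona savignyi	Ascidian	invertebrate,chordate-invertebrate
Skow	Saccoglossus kowalevskii	Acorn worm	invertebrate
Pfla	Ptychodera flava	Acorn worm	invertebrate
Spur	Strongylocentrotus purpuratus	Sea urchin	invertebrate
Cele	Caenorhabditis elegans	Nematode	invertebrate,protostome
Agam	Anopheles gambiae	Mosquito	invertebrate,protostome
Dmel	Drosophila melanogaster	Fruit fly	invertebrate,protostome
Amel	Apis mellifera	Honey bee	invertebrate,protostome
Ctel	Capitella teleta	Capitella	invertebrate,protostome
Obim	Octopus bimaculoides	Octopus	invertebrate,protostome
Hmag	Hydra magnipapillata	Hydra	invertebrate,non-bilaterian
Nvec	Nematostella vectensis	Sea anemone	invertebrate,non-bilaterian
Tadh	Trichoplax adhaerens	Trichoplax	invertebrate,non-bilaterian
Aque	Amphimedon queenslandica	Sponge	invertebrate,non-bilaterian
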