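# Fossil calibration priors for the three nested dating configurations.
# B1 = root calibration only; B2 = six priors with the Danzigia christelae
# (Emesinae) prior as an exponential with a 25 Ma hard minimum; B3 = seven
# priors including Paleoploiariola venosa, with the Emesinae prior switched
# to its normal variant.  Source values printed with European decimal commas
# (10,5 and 32,5) are transcribed as 10.5 and 32.5.
name	clade_taxa	kind	mean	sd_or_offset	configurations
Ceresopsis costalis	Reduviidae	normal	185	10	B1;B2;B3
Koenisbergia herczeki	Lophocustus sp.;Macrocephalus spp.;Phymata spp.	normal	45	7	B2;B3
Praecoris dominicana	Ptilonemus femoralis;Ptilocerus sp.	normal	37	5	B2;B3
Danzigia christelae	Emesaya incisa;Stenolemus sp.;Stenolemoides arizonensis;Mangabea barbiger;Ploiaria hirticornia;Empicoris sp.	normal	45	7	B3
Danzigia christelae	Emesaya incisa;Stenolemus sp.;Stenolemoides arizonensis;Mangabea barbiger;Ploiaria hirticornia;Empicoris sp.	exponential	10.5	25	B2
Paleoploiariola venosa	Ploiaria hirticornia;Empicoris sp.	normal	32.5	5	B3
Panstrongylus hispaniolae	Panstrongylus spp.;T. dimidiata;T. longipennis;T. mazzottii;T. mexicana;T. pallidipennis;T. phyllosoma;T. picturata;T. ryckmani;T. bruneri;T. rubrofasciata;T. barberi;T. protracta;T. gerstaeckeri;T. lecticularia;T. recurva;T. rubida;T. sanguisuga;Linshcosteus sp.;Pa. hirsuta	normal	37	5	B2;B3
Apicrenus fossilis	Arilus cristatus;Acanthiscium sp.	normal	37	5	B2;B3
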