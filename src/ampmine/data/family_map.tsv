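# Accession -> family map for candidate classification (editable).
# Columns: accession <TAB> family
# Families: buforin acipensin ubiquicidin lysozyme beta_thymosin crustin
#           paralithocin kazal alf other
# AP9xxxx accessions are synthetic placeholders used by the bundled
# transcriptome simulator; all others are APD3 accessions.
AP00308	buforin
AP00489	buforin
AP02811	acipensin
AP02813	acipensin
AP02096	ubiquicidin
AP02766	lysozyme
AP02533	beta_thymosin
AP01555	crustin
AP02625	crustin
AP02752	crustin
AP02753	crustin
AP02959	paralithocin
AP02960	paralithocin
AP02961	paralithocin
AP00208	paralithocin
AP03038	kazal
AP02147	alf
AP90101	paralithocin
AP90102	paralithocin
AP90103	paralithocin
AP90104	paralithocin
AP90105	paralithocin
AP90106	paralithocin
AP90107	paralithocin
AP90108	paralithocin
AP90201	crustin
AP90202	crustin
AP90203	crustin
AP90204	crustin
AP90205	crustin
AP90206	crustin
AP90207	crustin
AP90208	crustin
AP90301	alf
AP90302	alf
AP90303	alf
AP90304	alf
AP90305	alf
AP90306	alf
AP90307	alf
AP90308	alf
AP90401	kazal
AP90402	kazal
AP90403	kazal
AP90404	kazal
AP90405	kazal
AP90406	kazal
AP90407	kazal
AP90408	kazal
AP90501	buforin
AP90502	buforin
AP90503	buforin
AP90504	buforin
AP90505	buforin
AP90506	buforin
AP90507	buforin
AP90508	buforin
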