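taxonID,parentNameUsageID,scientificName,taxonRank,datasetName,conceptNote
T0001,,Celastrina ladon,species,switchboard,complex=Celastrina-ladon-complex; label=ladon
T0002,,Celastrina neglecta,species,switchboard,complex=Celastrina-ladon-complex; label=neglecta
T0003,,Celastrina lucia,species,switchboard,complex=Celastrina-ladon-complex; label=lucia
T0004,,Celastrina echo,species,switchboard,complex=Celastrina-ladon-complex; label=echo
T0005,,Celastrina humulus,species,switchboard,complex=Celastrina-ladon-complex; label=humulus
T0006,,Celastrina serotina,species,switchboard,complex=Celastrina-ladon-complex; label=serotina
T0007,,Celastrina idella,species,switchboard,complex=Celastrina-ladon-complex; label=idella
T0008,T0001,Celastrina ladon,species,NABA,
T0009,T0002,Celastrina ladon,species,NABA,
T0010,T0003,Celastrina ladon,species,NABA,
T0011,T0004,Celastrina ladon,species,NABA,
T0012,T0005,Celastrina ladon,species,NABA,
T0013,T0001,Celastrina ladon,species,OW,
T0014,T0002,Celastrina neglecta,species,OW,
T0015,T0003,Celastrina lucia,species,OW,
T0016,T0004,Celastrina echo,species,OW,
T0017,T0005,Celastrina humulus,species,OW,
T0018,T0003,Celastrina lucia,species,Pelham,
T0019,T0004,Celastrina echo,species,Pelham,
T0020,T0008,Celastrina ladon/neglecta,conglomerate,Illinois,assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0021,T0009,Celastrina ladon/neglecta,conglomerate,Illinois,assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0022,T0010,Celastrina ladon/neglecta,conglomerate,Illinois,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0023,T0011,Celastrina ladon/neglecta,conglomerate,Illinois,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0024,T0012,Celastrina ladon/neglecta,conglomerate,Illinois,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0025,T0008,Celastrina ladon,species,Iowa,assess; one name collects both local subtaxa under the authority's wide species concept
T0026,T0009,Celastrina ladon,species,Iowa,assess; one name collects both local subtaxa under the authority's wide species concept
T0027,T0010,Celastrina ladon,species,Iowa,subsumed; assess; one name collects both local subtaxa under the authority's wide species concept
T0028,T0011,Celastrina ladon,species,Iowa,subsumed; assess; one name collects both local subtaxa under the authority's wide species concept
T0029,T0012,Celastrina ladon,species,Iowa,subsumed; assess; one name collects both local subtaxa under the authority's wide species concept
T0030,T0008,Celastrina ladon/neglecta,conglomerate,Michigan,assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0031,T0009,Celastrina ladon/neglecta,conglomerate,Michigan,assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0032,T0010,Celastrina ladon/neglecta,conglomerate,Michigan,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0033,T0011,Celastrina ladon/neglecta,conglomerate,Michigan,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0034,T0012,Celastrina ladon/neglecta,conglomerate,Michigan,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0035,T0008,Celastrina ladon,species,Ohio,assess; program splits neglecta out of the authority's wide species concept
T0036,T0010,Celastrina ladon,species,Ohio,subsumed; assess; program splits neglecta out of the authority's wide species concept
T0037,T0011,Celastrina ladon,species,Ohio,subsumed; assess; program splits neglecta out of the authority's wide species concept
T0038,T0012,Celastrina ladon,species,Ohio,subsumed; assess; program splits neglecta out of the authority's wide species concept
T0039,T0009,Celastrina neglecta,species,Ohio,assess; split from the authority's wide species concept
T0040,T0008,Celastrina ladon/neglecta,conglomerate,Tennessee,assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0041,T0009,Celastrina ladon/neglecta,conglomerate,Tennessee,assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0042,T0010,Celastrina ladon/neglecta,conglomerate,Tennessee,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0043,T0011,Celastrina ladon/neglecta,conglomerate,Tennessee,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0044,T0012,Celastrina ladon/neglecta,conglomerate,Tennessee,subsumed; assess; conglomerate of field-indistinguishable taxa under the authority's wide species concept
T0045,T0013,Celastrina ladon,species,Florida,assess; concept interpretation contested across authorities; user must assess compatibility
T0046,T0014,Celastrina neglecta,species,Florida,assess; concept interpretation contested across authorities; user must assess compatibility
T0047,T0018,Celastrina lucia,species,Cascades,assess; lucia/echo segregates are difficult to distinguish near their range contact
T0048,T0019,Celastrina echo,species,Cascades,assess; lucia/echo segregates are difficult to distinguish near their range contact
T0049,T0019,Celastrina echo,species,MPG,only one member of the complex occurs locally
T0050,T0013,Celastrina ladon,species,Colorado,assess; concept interpretation contested across authorities; user must assess compatibility
T0051,T0017,Celastrina humulus,species,Colorado,assess; concept interpretation contested across authorities; user must assess compatibility
T0052,T0016,Celastrina ladon echo,subspecies,Orange County,local population unambiguous; trinomial reflects a wide-ladon interpretation
T0053,T0013,Celastrina ladon echo,subspecies,Orange County,subsumed; local population unambiguous; trinomial reflects a wide-ladon interpretation
T0054,T0015,Celastrina ladon echo,subspecies,Orange County,subsumed; local population unambiguous; trinomial reflects a wide-ladon interpretation
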