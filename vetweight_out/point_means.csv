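species,year,n_practices,n_animals,n_juveniles,pct_juveniles,point_mean_kg,ci95_kg,period_mean_full_kg,period_mean_adults_only_kg,kruskal_wallis.practice.statistic,kruskal_wallis.practice.p,kruskal_wallis.practice.n_groups,kruskal_wallis.group.statistic,kruskal_wallis.group.p,kruskal_wallis.group.n_groups
dog,2023,20,10000,965,9.65,16.636216348430857,"[16.332446900944063, 16.93998579591765]",16.358749406376482,16.77185482125509,28.627606894777273,0.07207278818337777,20,10.632369535578619,0.03102166592217746,5
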