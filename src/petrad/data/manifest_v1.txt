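# petrad feature manifest, version 1
# 154 IBSI-style feature identifiers in canonical output order.
# Families: stat (18), ih (23), ivh (7), loc (2), morph (9),
#           cm (25), rlm (16), szm (16), dzm (16), ngt (5), ngl (17)
stat.mean
stat.var
stat.skew
stat.kurt
stat.median
stat.min
stat.p10
stat.p90
stat.max
stat.iqr
stat.range
stat.mad
stat.rmad
stat.medad
stat.cov
stat.qcod
stat.energy
stat.rms
ih.mean
ih.var
ih.skew
ih.kurt
ih.median
ih.min
ih.p10
ih.p90
ih.max
ih.mode
ih.iqr
ih.range
ih.mad
ih.rmad
ih.medad
ih.cov
ih.qcod
ih.entropy
ih.uniformity
ih.max.grad
ih.max.grad.g
ih.min.grad
ih.min.grad.g
ivh.v10
ivh.v90
ivh.i10
ivh.i90
ivh.diff.v10.v90
ivh.diff.i10.i90
ivh.auc
loc.peak.local
loc.peak.global
morph.vol.approx
morph.area.approx
morph.av
morph.comp.1
morph.comp.2
morph.sph.dispr
morph.sphericity
morph.asphericity
morph.diam
cm.joint.max
cm.joint.avg
cm.joint.var
cm.joint.entr
cm.diff.avg
cm.diff.var
cm.diff.entr
cm.sum.avg
cm.sum.var
cm.sum.entr
cm.energy
cm.contrast
cm.dissimilarity
cm.inv.diff
cm.inv.diff.norm
cm.inv.diff.mom
cm.inv.diff.mom.norm
cm.inv.var
cm.corr
cm.auto.corr
cm.clust.tend
cm.clust.shade
cm.clust.prom
cm.info.corr.1
cm.info.corr.2
rlm.sre
rlm.lre
rlm.lgre
rlm.hgre
rlm.srlge
rlm.srhge
rlm.lrlge
rlm.lrhge
rlm.glnu
rlm.glnu.norm
rlm.rlnu
rlm.rlnu.norm
rlm.r.perc
rlm.gl.var
rlm.rl.var
rlm.rl.entr
szm.sze
szm.lze
szm.lgze
szm.hgze
szm.szlge
szm.szhge
szm.lzlge
szm.lzhge
szm.glnu
szm.glnu.norm
szm.zsnu
szm.zsnu.norm
szm.z.perc
szm.gl.var
szm.zs.var
szm.zs.entr
dzm.sde
dzm.lde
dzm.lgze
dzm.hgze
dzm.sdlge
dzm.sdhge
dzm.ldlge
dzm.ldhge
dzm.glnu
dzm.glnu.norm
dzm.zdnu
dzm.zdnu.norm
dzm.z.perc
dzm.gl.var
dzm.zd.var
dzm.zd.entr
ngt.coarseness
ngt.contrast
ngt.busyness
ngt.complexity
ngt.strength
ngl.lde
ngl.hde
ngl.lgce
ngl.hgce
ngl.ldlge
ngl.ldhge
ngl.hdlge
ngl.hdhge
ngl.glnu
ngl.glnu.norm
ngl.dcnu
ngl.dcnu.norm
ngl.dc.perc
ngl.gl.var
ngl.dc.var
ngl.dc.entr
ngl.dc.energy
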